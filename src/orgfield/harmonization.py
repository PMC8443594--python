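"""Registry identifier normalization and buffered spatial joins.

Certification registries report field locations as free-text Assessor's
Parcel Numbers (APN, canonical ``xxx-xxx-xx``) or Public Land Survey
Township-Range-Section triples, with no systematic formatting: several APNs
per cell, dashes missing, segments mis-sized, stray prefixes.  This module
repairs those strings deterministically, joins them to parcel / section
polygon layers by exact key match, and links polygons to crop fields with an
inward ("negative") buffer so that fields merely touching a parcel margin do
not join.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)


@dataclass
class NormalizedKey:
    kind: str  # "APN" | "TRS"
    key: str
    provenance: list[str] = field(default_factory=list)
    raw: str = ""


@dataclass
class MatchReport:
    """Accounting of registry-record linkage; counts are conserved:
    matched + unmatched + dropped == n_records."""

    n_records: int = 0
    n_matched: int = 0
    n_unmatched: int = 0
    n_dropped: int = 0
    fix_counts: dict[str, int] = field(default_factory=dict)
    audit: list[dict] = field(default_factory=list)

    def tally(self, fixes: Iterable[str]) -> None:
        for f in fixes:
            self.fix_counts[f] = self.fix_counts.get(f, 0) + 1

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records, "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched, "n_dropped": self.n_dropped,
            "fix_counts": self.fix_counts, "audit": self.audit,
        }


_SPLIT_RE = re.compile(r"[\n;,\s]+")


def split_multivalue(raw: str) -> list[str]:
    """Split a free-text cell into candidate identifier tokens.

    Separators are line breaks, semi-colons, commas and whitespace, in any
    combination; empty tokens are removed.
    """
    if raw is None:
        return []
    return [t for t in _SPLIT_RE.split(str(raw)) if t]


def _fix_segment(seg: str, width: int, fixes: list[str]) -> str:
    if len(seg) < width:
        fixes.append("pad_left")
        return seg.zfill(width)
    if len(seg) > width:
        fixes.append("trim_right")
        return seg[:width]
    return seg


def clean_apn(token: str) -> NormalizedKey | None:
    """Normalize an APN token to the canonical ``xxx-xxx-xx`` key.

    Rules, applied in order:

    * non-digit, non-dash characters are stripped;
    * a dashless token with >= 8 digits has dashes inserted after the 3rd,
      6th and 8th characters;
    * a dashless token with < 8 digits is dropped (returns ``None``);
    * segments are padded with a left zero or trimmed from the right to
      widths 3-3-2; segments beyond the third are dropped but recorded in
      provenance.

    The function is idempotent on its own output.
    """
    if not isinstance(token, str):
        raise TypeError(f"APN token must be a string, got {type(token).__name__}")
    fixes: list[str] = []
    cleaned = re.sub(r"[^0-9-]", "", token.strip())
    if cleaned != token.strip():
        fixes.append("stripped_nonnumeric")
    if "-" not in cleaned:
        digits = cleaned
        if len(digits) < 8:
            return None
        fixes.append("inserted_dashes")
        cleaned = "-".join(s for s in (digits[:3], digits[3:6], digits[6:8], digits[8:]) if s)
    segs = [s for s in cleaned.split("-") if s]
    if not segs:
        return None
    if len(segs) > 3:
        fixes.append("dropped_extra_segments")
        extra = segs[3:]
        segs = segs[:3]
    else:
        extra = []
    while len(segs) < 3:
        # under-segmented dashed tokens: treat missing trailing segments as empty
        segs.append("")
    key_segs = [
        _fix_segment(segs[0], 3, fixes),
        _fix_segment(segs[1], 3, fixes),
        _fix_segment(segs[2], 2, fixes),
    ]
    result = NormalizedKey(kind="APN", key="-".join(key_segs), provenance=fixes, raw=token)
    if extra:
        result.provenance.append("extra:" + "-".join(extra))
    return result


_TRS_PREFIX_RE = re.compile(r"^\s*(?:sec(?:tion)?\.?\s*|t(?=\d)|r(?=\d)|s(?=\d))", re.IGNORECASE)


def clean_trs(township: str, range_: str, section: str) -> NormalizedKey | None:
    """Normalize a Township/Range/Section triple to a concatenated key.

    Prefixes ("T", "R", "S", "Sec.", "Section") are stripped
    case-insensitively, the section number is zero-padded to two digits, and
    the three parts are concatenated (e.g. ``29S26E07``).  Returns ``None``
    (record flagged unmatched) if any component is empty.
    """
    parts = []
    for val in (township, range_, section):
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return None
        txt = _TRS_PREFIX_RE.sub("", str(val).strip()).strip()
        if not txt:
            return None
        parts.append(txt.upper())
    t, r, s = parts
    digits = re.sub(r"\D", "", s)
    if not digits:
        return None
    return NormalizedKey(kind="TRS", key=f"{t}{r}{int(digits):02d}",
                         raw=f"{township}|{range_}|{section}")


def normalize_registry(records: pd.DataFrame) -> tuple[list[dict], MatchReport]:
    """Clean every registry row into normalized keys (no joining yet).

    Each output entry is ``{"row": i, "year": y, "keys": [NormalizedKey, ...],
    "dropped": [tokens]}``.
    """
    report = MatchReport(n_records=len(records))
    entries = []
    for i, rec in records.reset_index(drop=True).iterrows():
        keys: list[NormalizedKey] = []
        dropped: list[str] = []
        raw_apn = rec.get("raw_apn", "")
        for token in split_multivalue(raw_apn if isinstance(raw_apn, str) else ""):
            nk = clean_apn(token)
            if nk is None:
                dropped.append(token)
                report.tally(["dropped_short_apn"])
            else:
                keys.append(nk)
                report.tally(nk.provenance)
        trs = clean_trs(rec.get("raw_township", ""), rec.get("raw_range", ""),
                        rec.get("raw_section", ""))
        if trs is not None:
            keys.append(trs)
        entries.append({"row": int(i), "year": rec.get("year"),
                        "keys": keys, "dropped": dropped})
    return entries, report


def join_registry(records: pd.DataFrame, parcels: pd.DataFrame,
                  sections: pd.DataFrame):
    """Exact-match normalized registry keys against parcel and section layers.

    Returns ``(matched_parcels, matched_sections, report)`` where the matches
    are DataFrames of ``(year, key)`` joined rows of the respective layer.  A
    record counts as matched if at least one of its keys matched; records
    whose every token was dropped count as dropped.
    """
    entries, report = normalize_registry(records)
    apn_keys = set(parcels["apn"]) if "apn" in parcels.columns else set()
    if "apn" in parcels.columns and parcels.apn.duplicated().any():
        logger.warning("duplicate APN keys in parcel layer; keeping all matches")
    trs_keys = set(sections["trs"]) if "trs" in sections.columns else set()

    matched_parcel_rows, matched_section_rows = [], []
    for entry in entries:
        hit = False
        for nk in entry["keys"]:
            if nk.kind == "APN" and nk.key in apn_keys:
                hit = True
                matched_parcel_rows.append({"year": entry["year"], "apn": nk.key})
            elif nk.kind == "TRS" and nk.key in trs_keys:
                hit = True
                matched_section_rows.append({"year": entry["year"], "trs": nk.key})
        if hit:
            report.n_matched += 1
        elif entry["keys"]:
            report.n_unmatched += 1
        else:
            report.n_dropped += 1
        report.audit.append({
            "row": entry["row"], "year": entry["year"],
            "keys": [(k.kind, k.key, list(k.provenance)) for k in entry["keys"]],
            "dropped_tokens": entry["dropped"], "matched": hit,
        })

    matched_parcels = (pd.DataFrame(matched_parcel_rows, columns=["year", "apn"])
                       .drop_duplicates().merge(parcels, on="apn"))
    matched_sections = (pd.DataFrame(matched_section_rows, columns=["year", "trs"])
                        .drop_duplicates().merge(sections, on="trs"))
    return matched_parcels, matched_sections, report


def buffered_field_join(polygons: pd.DataFrame, fields: pd.DataFrame,
                        buffer_m: float = 50.0) -> pd.DataFrame:
    """Join fields to polygons after shrinking each polygon inward.

    Each source polygon is eroded by ``|buffer_m|`` meters; a field joins if
    its geometry intersects the eroded polygon.  Polygons that vanish under
    erosion are excluded (and logged).  Returns the joined rows of ``fields``
    with a ``source_index`` column pointing back into ``polygons``; when the
    polygon table has a ``year`` column the join is year-aware.

    The candidate set weakly shrinks as ``|buffer_m|`` grows.
    """
    dist = -abs(buffer_m)
    field_geoms = list(fields.geometry)
    tree = STRtree(field_geoms)
    out = []
    for idx, row in polygons.reset_index(drop=True).iterrows():
        geom = row["geometry"]
        if geom is None or not geom.is_valid:
            logger.warning("skipping invalid polygon at row %d", idx)
            continue
        shrunk = geom.buffer(dist)
        if shrunk.is_empty:
            logger.info("polygon at row %d vanished under %.0f m erosion", idx, buffer_m)
            continue
        for j in tree.query(shrunk, predicate="intersects"):
            rec = fields.iloc[int(j)].to_dict()
            rec["source_index"] = int(idx)
            if "year" in polygons.columns:
                rec["source_year"] = row["year"]
            out.append(rec)
    cols = list(fields.columns) + ["source_index"] + (
        ["source_year"] if "year" in polygons.columns else [])
    return pd.DataFrame(out, columns=cols)


def harmonize(registry: pd.DataFrame, parcels: pd.DataFrame,
              sections: pd.DataFrame, fields: pd.DataFrame,
              buffer_m: float = 50.0):
    """Full identification front-end: clean, join, buffer, flag candidates.

    Returns ``(candidates, report)`` where ``candidates`` is the set of
    field-year keys (permit, site, year) flagged as registry-organic
    candidates for the matching year.
    """
    matched_parcels, matched_sections, report = join_registry(registry, parcels, sections)
    frames = []
    for matched in (matched_parcels, matched_sections):
        if len(matched) == 0:
            continue
        joined = buffered_field_join(matched, fields, buffer_m=buffer_m)
        if len(joined):
            joined = joined[joined.year == joined.source_year]
            frames.append(joined[["permit", "site", "year"]])
    if frames:
        candidates = pd.concat(frames).drop_duplicates().reset_index(drop=True)
    else:
        candidates = pd.DataFrame(columns=["permit", "site", "year"])
    return candidates, report
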