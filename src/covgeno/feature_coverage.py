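"""Per-feature and per-exon sequencing depth under a mapping-filter profile.

Depth is computed on the reference span of each read, clipped to exon
boundaries; the mean depth of a feature is the length-weighted mean over its
exons, identical to averaging the per-base pileup.  A read counts as
overlapping an exon when at least one base of its span intersects it.

The multimap fraction of an exon is the share of multimapped reads among all
*duplicate-free* reads overlapping it, independent of the depth profile:
duplicates are removed first, mirroring the order of the filtering contract
(duplicates, then mapping quality).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import (
    ALL_PROFILE,
    UNIQUE_PROFILE,
    FilterProfile,
    GeneFeature,
    ReadRecord,
    ValidationError,
)

DEPTH_COLUMNS = [
    "sample_id", "feature_id", "exon_index", "mean_depth", "n_reads",
    "multimap_fraction", "profile_name",
]


def filter_reads(
    reads: Iterable[ReadRecord], profile: FilterProfile
) -> list[ReadRecord]:
    """Apply a mapping-filter profile; order is preserved."""
    out = []
    for r in reads:
        if profile.drop_duplicates and r.is_duplicate:
            continue
        if r.mapq < profile.mapq_min:
            continue
        if not profile.keep_multimapped and r.is_multimapped:
            continue
        out.append(r)
    return out


def per_base_depth(
    reads: Iterable[ReadRecord], interval: tuple[str, int, int]
) -> np.ndarray:
    """Pileup depth vector over ``interval = (chrom, start, end)``.

    Position ``i`` of the result counts the reads whose reference span
    covers ``start + i``.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValidationError(f"empty interval [{start}, {end})")
    diff = np.zeros(end - start + 1, dtype=np.int64)
    for r in reads:
        if r.chrom != chrom:
            continue
        lo = max(r.start, start)
        hi = min(r.end, end)
        if hi > lo:
            diff[lo - start] += 1
            diff[hi - start] -= 1
    return np.cumsum(diff[:-1])


class _SampleIndex:
    """One sample's reads, indexed by chromosome and sorted by start.

    Exon queries touch only the candidate slice whose starts fall within
    ``[exon_start - max_read_length, exon_end)``, so per-exon cost scales
    with local — not total — read count.
    """

    def __init__(self, reads: Sequence[ReadRecord]):
        by_chrom: dict[str, list[ReadRecord]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._chroms: dict[str, dict[str, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            n = len(recs)
            start = np.fromiter((r.start for r in recs), dtype=np.int64, count=n)
            order = np.argsort(start, kind="stable")
            start = start[order]
            end = np.fromiter((r.end for r in recs), dtype=np.int64, count=n)[order]
            self._chroms[chrom] = {
                "start": start,
                "end": end,
                "mapq": np.fromiter((r.mapq for r in recs), dtype=np.int64, count=n)[order],
                "dup": np.fromiter((r.is_duplicate for r in recs), dtype=bool, count=n)[order],
                "mm": np.fromiter((r.is_multimapped for r in recs), dtype=bool, count=n)[order],
                "max_len": int((end - start).max()) if n else 0,
            }

    def overlapping(
        self, chrom: str, s: int, e: int
    ) -> dict[str, np.ndarray] | None:
        """Columns for reads with >=1 base inside [s, e), or None if empty."""
        cols = self._chroms.get(chrom)
        if cols is None:
            return None
        lo = int(np.searchsorted(cols["start"], s - cols["max_len"], side="left"))
        hi = int(np.searchsorted(cols["start"], e, side="left"))
        if hi <= lo:
            return None
        sl = slice(lo, hi)
        mask = cols["end"][sl] > s
        if not mask.any():
            return None
        return {
            "start": cols["start"][sl][mask],
            "end": cols["end"][sl][mask],
            "mapq": cols["mapq"][sl][mask],
            "dup": cols["dup"][sl][mask],
            "mm": cols["mm"][sl][mask],
            "index": np.arange(lo, hi)[mask],  # stable ids for feature-level dedup
        }


def _profile_mask(cand: dict[str, np.ndarray], profile: FilterProfile) -> np.ndarray:
    mask = cand["mapq"] >= profile.mapq_min
    if profile.drop_duplicates:
        mask &= ~cand["dup"]
    if not profile.keep_multimapped:
        mask &= ~cand["mm"]
    return mask


def _mean_depth(cand: dict[str, np.ndarray], mask: np.ndarray, s: int, e: int) -> float:
    if not mask.any():
        return 0.0
    span = np.minimum(cand["end"][mask], e) - np.maximum(cand["start"][mask], s)
    return float(span.sum()) / (e - s)


def feature_mean_depth(
    reads: Sequence[ReadRecord], feature: GeneFeature, profile: FilterProfile
) -> float:
    """Length-weighted mean depth over a feature's exons after filtering."""
    total_len = feature.exon_length
    if total_len == 0:
        raise ValidationError(f"{feature.feature_id}: zero-length exon set")
    index = _SampleIndex(list(reads))
    covered = 0.0
    for s, e in feature.exons:
        cand = index.overlapping(feature.chrom, s, e)
        if cand is None:
            continue
        covered += _mean_depth(cand, _profile_mask(cand, profile), s, e) * (e - s)
    return covered / total_len


def build_depth_table(
    reads_by_sample: Mapping[str, Sequence[ReadRecord]],
    features: Sequence[GeneFeature],
    profiles: Sequence[FilterProfile] = (UNIQUE_PROFILE, ALL_PROFILE),
    per_exon: bool = True,
) -> pd.DataFrame:
    """Depth table with one row per (sample, feature[, exon], profile).

    ``exon_index`` is the exon's string index, or ``"ALL"`` for the
    whole-feature length-weighted row.  ``n_reads`` counts profile-surviving
    reads overlapping the exon (feature rows count reads overlapping any
    exon once); ``multimap_fraction`` is computed over duplicate-free reads
    regardless of profile and is 0 when no reads overlap.
    """
    rows: list[dict[str, object]] = []
    for sample_id in reads_by_sample:
        index = _SampleIndex(list(reads_by_sample[sample_id]))
        for feature in features:
            total_len = feature.exon_length
            exon_cands = [
                index.overlapping(feature.chrom, s, e) for s, e in feature.exons
            ]
            for profile in profiles:
                covered = 0.0
                feat_ids: list[np.ndarray] = []
                feat_nodup_n = 0
                feat_mm_n = 0
                seen_nodup: set[int] = set()
                for i, (exon, cand) in enumerate(zip(feature.exons, exon_cands)):
                    s, e = exon
                    if cand is None:
                        depth, n_reads, mm_frac = 0.0, 0, 0.0
                    else:
                        keep = _profile_mask(cand, profile)
                        depth = _mean_depth(cand, keep, s, e)
                        n_reads = int(keep.sum())
                        nodup = ~cand["dup"]
                        n_nodup = int(nodup.sum())
                        mm_frac = (
                            float(cand["mm"][nodup].sum()) / n_nodup if n_nodup else 0.0
                        )
                        feat_ids.append(cand["index"][keep])
                        for rid, is_mm in zip(
                            cand["index"][nodup].tolist(), cand["mm"][nodup].tolist()
                        ):
                            if rid not in seen_nodup:
                                seen_nodup.add(rid)
                                feat_nodup_n += 1
                                feat_mm_n += int(is_mm)
                    covered += depth * (e - s)
                    if per_exon:
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "feature_id": feature.feature_id,
                                "exon_index": str(i),
                                "mean_depth": depth,
                                "n_reads": n_reads,
                                "multimap_fraction": mm_frac,
                                "profile_name": profile.profile_name,
                            }
                        )
                n_feat_reads = (
                    int(np.unique(np.concatenate(feat_ids)).size) if feat_ids else 0
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "feature_id": feature.feature_id,
                        "exon_index": "ALL",
                        "mean_depth": covered / total_len,
                        "n_reads": n_feat_reads,
                        "multimap_fraction": (
                            feat_mm_n / feat_nodup_n if feat_nodup_n else 0.0
                        ),
                        "profile_name": profile.profile_name,
                    }
                )
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)
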