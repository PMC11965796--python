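"""Three-way coverage-ratio genotyping of a tandem-array deletion.

A sample's deletion-ratio statistic is

    r = mean depth over deletion-member genes / mean depth over retained
        array-reference genes,

computed under the uniquely-mapped filter profile.  A diploid carrying the
deletion on neither, one, or both haplotypes is expected at r ~ 1, ~ 0.5 and
~ 0 respectively, so classification is a step function of r:

    HomoDel   iff r <  homodel_max   (default 0.10)
    Het       iff het_low <= r <= het_high   (default [0.35, 0.65])
    HomoRef   iff r >= homoref_min   (default 0.80)
    Ambiguous otherwise

Exons flagged as multimapping artifacts (conserved exons shared with a
retained paralog) can be excluded from the deleted-set mean: the remaining
exons of the affected gene are re-averaged with length weights.

Per-gene means are unweighted across genes by default — capture efficiency
varies per target, so a long gene should not dominate the ratio; a
length-weighted variant is available via ``gene_weighting="length"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

import numpy as np
import pandas as pd

from .locus_model import GeneFeature, ValidationError

CALL_CLASSES = ("HomoRef", "Het", "HomoDel", "Ambiguous")
UNINFORMATIVE = "Uninformative"


class UninformativeSampleError(ValueError):
    """Reference depth is zero or missing — capture failed for this sample."""


@dataclass(frozen=True)
class GenotypeThresholds:
    """Ratio bands for the three-way deletion call.

    The Het band is closed, the HomoDel bound open, per the classification
    rule above.  Ratios between bands are Ambiguous rather than forced into
    a class, so QC failures stay visible.
    """

    homodel_max: float = 0.10
    het_low: float = 0.35
    het_high: float = 0.65
    homoref_min: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.homodel_max < self.het_low < self.het_high < self.homoref_min:
            raise ValidationError(
                "thresholds must satisfy 0 < homodel_max < het_low < het_high "
                "< homoref_min"
            )


@dataclass(frozen=True)
class SVGenotypeCall:
    """One sample's deletion-ratio statistic and its classification."""

    sample_id: str
    ratio: float
    call: str
    deleted_mean: float
    reference_mean: float
    excluded_exons: tuple[tuple[str, int], ...]
    thresholds: GenotypeThresholds


def classify_sv(r: float, thresholds: GenotypeThresholds | None = None) -> str:
    """Map a deletion ratio to {HomoRef, Het, HomoDel, Ambiguous}."""
    t = thresholds or GenotypeThresholds()
    if r < 0:
        raise ValidationError(f"ratio {r} < 0")
    if r < t.homodel_max:
        return "HomoDel"
    if t.het_low <= r <= t.het_high:
        return "Het"
    if r >= t.homoref_min:
        return "HomoRef"
    return "Ambiguous"


def _gene_mean_excluding(
    sample_rows: pd.DataFrame,
    feature: GeneFeature,
    excluded: Collection[tuple[str, int]],
) -> float | None:
    """Length-weighted mean depth of a gene after dropping excluded exons.

    Returns None when every exon is excluded (gene drops out of the
    deleted-set mean) or when no rows are present.
    """
    kept = [
        (i, e) for i, e in enumerate(feature.exons)
        if (feature.feature_id, i) not in excluded
    ]
    if not kept:
        return None
    rows = sample_rows[sample_rows["feature_id"] == feature.feature_id]
    exon_rows = rows[rows["exon_index"] != "ALL"]
    if exon_rows.empty:
        return None
    depth_by_exon = dict(
        zip(exon_rows["exon_index"].astype(int), exon_rows["mean_depth"])
    )
    total = 0.0
    total_len = 0
    for i, (s, e) in kept:
        if i not in depth_by_exon:
            return None
        total += depth_by_exon[i] * (e - s)
        total_len += e - s
    return total / total_len


def deletion_ratio(
    depth_table: pd.DataFrame,
    sample_id: str,
    features: Sequence[GeneFeature],
    excluded_exons: Collection[tuple[str, int]] = (),
    profile: str = "unique",
    gene_weighting: str = "uniform",
) -> tuple[float, float, float]:
    """(ratio, deleted_mean, reference_mean) for one sample.

    ``excluded_exons`` are (feature_id, exon_index) pairs removed from the
    deleted-set computation before averaging; affected genes are re-averaged
    over their remaining exons.
    """
    excluded = set(excluded_exons)
    deleted = [f for f in features if f.role == "deletion_member"]
    reference = [f for f in features if f.role == "array_reference"]
    if not deleted or not reference:
        raise ValidationError("need >=1 deletion_member and >=1 array_reference")

    rows = depth_table[
        (depth_table["sample_id"] == sample_id)
        & (depth_table["profile_name"] == profile)
    ]
    if rows.empty:
        raise UninformativeSampleError(f"no depth rows for sample {sample_id!r}")

    def gene_means(genes: Sequence[GeneFeature], apply_exclusions: bool) -> list[tuple[float, int]]:
        means: list[tuple[float, int]] = []
        for f in genes:
            has_exclusion = apply_exclusions and any(
                (f.feature_id, i) in excluded for i in range(len(f.exons))
            )
            if has_exclusion:
                m = _gene_mean_excluding(rows, f, excluded)
                if m is None:
                    continue
                kept_len = sum(
                    e - s for i, (s, e) in enumerate(f.exons)
                    if (f.feature_id, i) not in excluded
                )
                means.append((m, kept_len))
            else:
                all_row = rows[
                    (rows["feature_id"] == f.feature_id)
                    & (rows["exon_index"] == "ALL")
                ]
                if all_row.empty:
                    raise UninformativeSampleError(
                        f"sample {sample_id!r}: no depth row for {f.feature_id}"
                    )
                means.append((float(all_row["mean_depth"].iloc[0]), f.exon_length))
        return means

    del_means = gene_means(deleted, apply_exclusions=True)
    ref_means = gene_means(reference, apply_exclusions=False)
    if not del_means:
        raise UninformativeSampleError(
            f"sample {sample_id!r}: all deletion-member exons excluded"
        )

    def aggregate(means: list[tuple[float, int]]) -> float:
        if gene_weighting == "length":
            weights = np.array([w for _, w in means], dtype=float)
            values = np.array([m for m, _ in means], dtype=float)
            return float(np.average(values, weights=weights))
        return float(np.mean([m for m, _ in means]))

    deleted_mean = aggregate(del_means)
    reference_mean = aggregate(ref_means)
    if reference_mean <= 0:
        raise UninformativeSampleError(
            f"sample {sample_id!r}: reference mean depth is 0 (capture failure)"
        )
    return deleted_mean / reference_mean, deleted_mean, reference_mean


def genotype_cohort(
    depth_table: pd.DataFrame,
    features: Sequence[GeneFeature],
    thresholds: GenotypeThresholds | None = None,
    artifact_flags: Collection[tuple[str, int]] = (),
    cohort: pd.DataFrame | None = None,
    profile: str = "unique",
    gene_weighting: str = "uniform",
) -> tuple[list[SVGenotypeCall], pd.DataFrame]:
    """Genotype every sample; returns (calls, per-region/class count summary).

    Samples whose depth rows are missing or whose reference depth is zero
    yield an ``Uninformative`` record rather than aborting the cohort.
    ``artifact_flags`` may be (feature_id, exon_index) pairs or objects with
    those attributes (e.g. :class:`~covgeno.paralog_artifacts.ArtifactFlag`).
    """
    t = thresholds or GenotypeThresholds()
    excluded = tuple(sorted(_as_exon_pairs(artifact_flags)))
    if cohort is not None:
        sample_ids = list(cohort["sample_id"])
        regions = dict(zip(cohort["sample_id"], cohort["region_label"]))
    else:
        sample_ids = sorted(depth_table["sample_id"].unique())
        regions = {}

    by_sample = {
        sid: frame for sid, frame in depth_table.groupby("sample_id", sort=False)
    }
    empty = depth_table.iloc[0:0]
    calls: list[SVGenotypeCall] = []
    for sample_id in sample_ids:
        try:
            r, dmean, rmean = deletion_ratio(
                by_sample.get(sample_id, empty), sample_id, features, excluded,
                profile, gene_weighting,
            )
            call = classify_sv(r, t)
        except UninformativeSampleError:
            r, dmean, rmean, call = float("nan"), float("nan"), float("nan"), UNINFORMATIVE
        calls.append(
            SVGenotypeCall(
                sample_id=sample_id, ratio=r, call=call, deleted_mean=dmean,
                reference_mean=rmean, excluded_exons=excluded, thresholds=t,
            )
        )

    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        region = str(regions.get(c.sample_id, "all"))
        counts[(region, c.call)] = counts.get((region, c.call), 0) + 1
    summary = pd.DataFrame(
        [
            {"region_label": region, "call": call, "n": n}
            for (region, call), n in sorted(counts.items())
        ],
        columns=["region_label", "call", "n"],
    )
    return calls, summary


def calls_to_frame(calls: Iterable[SVGenotypeCall]) -> pd.DataFrame:
    """Tabular view of genotype calls for writing/joining."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "ratio": c.ratio,
                "call": c.call,
                "deleted_mean": c.deleted_mean,
                "reference_mean": c.reference_mean,
                "n_excluded_exons": len(c.excluded_exons),
            }
            for c in calls
        ]
    )


def _as_exon_pairs(flags: Collection) -> set[tuple[str, int]]:
    pairs: set[tuple[str, int]] = set()
    for f in flags:
        if isinstance(f, tuple):
            pairs.add((str(f[0]), int(f[1])))
        else:
            pairs.add((str(f.feature_id), int(f.exon_index)))
    return pairs
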