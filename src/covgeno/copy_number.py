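"""Diploid copy-number estimation for a multi-copy gene family.

The family's dose is read off targeted-capture depth at designated target
exons (by default exons 2 and 3 of each family gene, which carry the
distinguishing capture signal) normalised against a panel of single-copy
reference genes:

    cn = 2 * target_mean / reference_mean

The factor 2 makes the estimate a *diploid* copy number, since the reference
genes are present at two copies per genome.  Depth is computed under the
"all" profile (multimapped reads kept): members of a high-identity family
cross-map among themselves, so a uniqueness filter discards most of the
family's reads and systematically underestimates its dose.

Within each target gene the designated exons are averaged with length
weights; the per-gene means are then averaged across genes.  The reference
mean is an arithmetic mean over reference genes by default; a median is
available for robustness to a single failed capture target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import GeneFeature, ValidationError
from .sv_genotyper import UninformativeSampleError


@dataclass(frozen=True)
class CopyNumberEstimate:
    """One sample's diploid copy-number estimate and its components."""

    sample_id: str
    cn: float
    target_mean: float
    reference_mean: float
    n_reference_genes: int
    profile_name: str


def estimate_copy_number(
    depth_table: pd.DataFrame,
    sample_id: str,
    cn_target_exons: Sequence[tuple[str, int]],
    cn_reference_genes: Sequence[str],
    profile: str = "all",
    reference_agg: str = "mean",
    features: Mapping[str, GeneFeature] | None = None,
) -> CopyNumberEstimate:
    """Estimate one sample's diploid copy number.

    ``cn_target_exons`` are (feature_id, exon_index) pairs; exon designation
    comes from the feature file, not position heuristics.  ``features`` (a
    feature_id -> GeneFeature mapping) supplies exon lengths for the
    within-gene length weighting; without it exons are weighted equally.
    """
    if not cn_target_exons:
        raise ValidationError("need >=1 copy-number target exon")
    if not cn_reference_genes:
        raise ValidationError("need >=1 single-copy reference gene")
    rows = depth_table[
        (depth_table["sample_id"] == sample_id)
        & (depth_table["profile_name"] == profile)
    ]
    if rows.empty:
        raise UninformativeSampleError(f"no depth rows for sample {sample_id!r}")

    # length-weighted mean of designated exons within each gene, then an
    # unweighted average across genes
    by_gene: dict[str, list[tuple[float, int]]] = {}
    for feature_id, exon_index in cn_target_exons:
        row = rows[
            (rows["feature_id"] == feature_id)
            & (rows["exon_index"] == str(exon_index))
        ]
        if row.empty:
            raise UninformativeSampleError(
                f"sample {sample_id!r}: no depth row for {feature_id} exon {exon_index}"
            )
        depth = float(row["mean_depth"].iloc[0])
        if features is not None and feature_id in features:
            s, e = features[feature_id].exons[exon_index]
            length = e - s
        else:
            length = 1
        by_gene.setdefault(feature_id, []).append((depth, length))
    gene_means = [
        float(np.average([d for d, _ in pairs], weights=[w for _, w in pairs]))
        for pairs in by_gene.values()
    ]
    target_mean = float(np.mean(gene_means))

    ref_depths = []
    for gene in cn_reference_genes:
        row = rows[(rows["feature_id"] == gene) & (rows["exon_index"] == "ALL")]
        if row.empty:
            raise UninformativeSampleError(
                f"sample {sample_id!r}: no depth row for reference gene {gene}"
            )
        ref_depths.append(float(row["mean_depth"].iloc[0]))
    if reference_agg == "median":
        reference_mean = float(np.median(ref_depths))
    else:
        reference_mean = float(np.mean(ref_depths))
    if reference_mean <= 0:
        raise UninformativeSampleError(
            f"sample {sample_id!r}: reference mean depth is 0 (capture failure)"
        )
    return CopyNumberEstimate(
        sample_id=sample_id,
        cn=2.0 * target_mean / reference_mean,
        target_mean=target_mean,
        reference_mean=reference_mean,
        n_reference_genes=len(cn_reference_genes),
        profile_name=profile,
    )


def copy_number_cohort(
    depth_table: pd.DataFrame,
    features: Sequence[GeneFeature],
    cohort: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    target_exon_indices: tuple[int, ...] = (1, 2),
    profile: str = "all",
    reference_agg: str = "mean",
) -> pd.DataFrame:
    """Copy-number estimates for every sample, joined with region and SV call.

    Target exons default to exon 2 and exon 3 (0-based indices 1 and 2) of
    every ``cn_target`` feature; reference genes are the ``cn_reference``
    features.  Per-sample failures are recorded as rows with ``status``
    "uninformative" rather than aborting the cohort.
    """
    feature_map = {f.feature_id: f for f in features}
    target_exons = [
        (f.feature_id, i)
        for f in features
        if f.role == "cn_target"
        for i in target_exon_indices
        if i < len(f.exons)
    ]
    reference_genes = [f.feature_id for f in features if f.role == "cn_reference"]
    if cohort is not None:
        sample_ids = list(cohort["sample_id"])
    else:
        sample_ids = sorted(depth_table["sample_id"].unique())

    by_sample = {
        sid: frame for sid, frame in depth_table.groupby("sample_id", sort=False)
    }
    empty = depth_table.iloc[0:0]
    rows: list[dict[str, object]] = []
    for sample_id in sample_ids:
        try:
            est = estimate_copy_number(
                by_sample.get(sample_id, empty), sample_id, target_exons, reference_genes,
                profile=profile, reference_agg=reference_agg, features=feature_map,
            )
            rows.append(
                {
                    "sample_id": sample_id, "cn": est.cn,
                    "target_mean": est.target_mean,
                    "reference_mean": est.reference_mean,
                    "n_reference_genes": est.n_reference_genes,
                    "profile_name": est.profile_name, "status": "ok",
                }
            )
        except (UninformativeSampleError, ValidationError):
            rows.append(
                {
                    "sample_id": sample_id, "cn": float("nan"),
                    "target_mean": float("nan"), "reference_mean": float("nan"),
                    "n_reference_genes": len(reference_genes),
                    "profile_name": profile, "status": "uninformative",
                }
            )
    out = pd.DataFrame(rows)
    if cohort is not None:
        out = out.merge(
            cohort[["sample_id", "region_label"]], on="sample_id", how="left"
        )
    if calls is not None:
        out = out.merge(calls[["sample_id", "call"]], on="sample_id", how="left")
    return out
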