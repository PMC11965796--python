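"""Rank-sum association tests and genotype-frequency summaries.

Tests whether a quantitative trait (here: estimated gene-family copy
number) differs between deletion-genotype classes using the Wilcoxon/
Mann-Whitney rank-sum test, and summarises genotype counts and the
deletion-allele frequency per region.

The U statistic uses midranks.  For small tie-free samples
(n1 + n2 <= 12) the p-value is exact, by full enumeration of all
C(n1+n2, n1) group labelings; otherwise a normal approximation with tie
correction and continuity correction is used.  Two-sided p-values follow
the doubling convention: p = min(1, 2 * smaller tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .locus_model import ValidationError

#: largest n1 + n2 for which the exact enumeration path is used (<= 924 labelings)
EXACT_LIMIT = 12

COMPARISONS = (
    ("HomoRef_vs_HomoDel", "HomoRef", "HomoDel"),
    ("Het_vs_HomoRef", "Het", "HomoRef"),
    ("Het_vs_HomoDel", "Het", "HomoDel"),
)


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U of the first sample and its two-sided p-value."""

    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    tie_corrected: bool


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], continuity: bool = True
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    ``u_statistic`` is U of the first sample: the number of (x, y) pairs
    with x > y, counting ties as 1/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2

    if not has_ties and n1 + n2 <= EXACT_LIMIT:
        p = _exact_p(ranks, n1, u1)
        return RankSumResult(u1, n1, n2, p, "exact", False)

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        # all observations tied: no evidence either way
        return RankSumResult(u1, n1, n2, 1.0, "normal_approx", True)
    cc = 0.5 if continuity else 0.0
    z = (abs(u1 - mean_u) - cc) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return RankSumResult(u1, n1, n2, p, "normal_approx", has_ties)


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n, n1) labelings of the ranks."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    u_values = [
        sum(ranks[i] for i in combo) - offset
        for combo in combinations(range(n), n1)
    ]
    total = len(u_values)
    le = sum(1 for u in u_values if u <= u_obs + 1e-12)
    ge = sum(1 for u in u_values if u >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(le, ge) / total)


def genotype_cn_association(
    calls: pd.DataFrame, cn_estimates: pd.DataFrame
) -> dict[str, RankSumResult | None]:
    """Rank-sum tests of copy number between deletion-genotype classes.

    Performs the three pairwise comparisons HomoRef vs HomoDel, Het vs
    HomoRef and Het vs HomoDel on samples joined by id.  Ambiguous and
    uninformative calls are excluded.  A comparison with an empty group is
    reported as None (not evaluable); the others proceed.
    """
    merged = calls[["sample_id", "call"]].merge(
        cn_estimates[["sample_id", "cn"]], on="sample_id", how="inner"
    )
    merged = merged[merged["call"].isin(["HomoRef", "Het", "HomoDel"])]
    merged = merged.dropna(subset=["cn"])
    groups = {
        g: merged.loc[merged["call"] == g, "cn"].to_numpy()
        for g in ("HomoRef", "Het", "HomoDel")
    }
    results: dict[str, RankSumResult | None] = {}
    for name, a, b in COMPARISONS:
        if len(groups[a]) == 0 or len(groups[b]) == 0:
            results[name] = None
        else:
            results[name] = rank_sum_test(groups[a], groups[b])
    return results


def association_to_frame(
    results: Mapping[str, RankSumResult | None]
) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        if res is None:
            rows.append(
                {
                    "comparison": name, "u_statistic": float("nan"),
                    "n1": 0, "n2": 0, "p_two_sided": float("nan"),
                    "method": "not_evaluable", "tie_corrected": False,
                }
            )
        else:
            rows.append(
                {
                    "comparison": name, "u_statistic": res.u_statistic,
                    "n1": res.n1, "n2": res.n2,
                    "p_two_sided": res.p_two_sided, "method": res.method,
                    "tie_corrected": res.tie_corrected,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "u_statistic", "n1", "n2", "p_two_sided", "method",
            "tie_corrected",
        ],
    )


def frequency_summary(
    calls: pd.DataFrame, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Genotype counts and deletion-allele frequency per region and overall.

    q = (2 * HomoDel + Het) / (2 * (HomoRef + Het + HomoDel)); Ambiguous and
    uninformative samples are counted but excluded from the denominator.
    """
    df = calls[["sample_id", "call"]].copy()
    if cohort is not None:
        df = df.merge(
            cohort[["sample_id", "region_label"]], on="sample_id", how="left"
        )
    else:
        df["region_label"] = "all"
    df["region_label"] = df["region_label"].fillna("unknown")

    def summarise(group: pd.DataFrame, label: str) -> dict[str, object]:
        counts = group["call"].value_counts()
        n_ref = int(counts.get("HomoRef", 0))
        n_het = int(counts.get("Het", 0))
        n_del = int(counts.get("HomoDel", 0))
        n_amb = int(counts.get("Ambiguous", 0)) + int(counts.get("Uninformative", 0))
        denom = 2 * (n_ref + n_het + n_del)
        q = (2 * n_del + n_het) / denom if denom else float("nan")
        return {
            "region_label": label, "n": len(group), "HomoRef": n_ref,
            "Het": n_het, "HomoDel": n_del, "Ambiguous": n_amb,
            "deletion_allele_freq": q,
        }

    rows = [
        summarise(group, str(region))
        for region, group in df.groupby("region_label", sort=True)
    ]
    rows.append(summarise(df, "overall"))
    return pd.DataFrame(
        rows,
        columns=[
            "region_label", "n", "HomoRef", "Het", "HomoDel", "Ambiguous",
            "deletion_allele_freq",
        ],
    )
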