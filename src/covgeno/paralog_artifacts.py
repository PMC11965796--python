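"""Paralog sequence identity and conserved-exon multimapping diagnosis.

Reads derived from a retained paralog can align equally well to a
near-identical exon of a *deleted* paralog, producing spurious coverage
peaks on genes that are in fact absent from the sample.  This module
quantifies pairwise identity between paralog exons (optimal global
alignment) and flags deletion-member exons that are either highly similar
to a retained paralog or dominated by multimapped reads across the cohort.
Flagged exons feed the genotyper's exclusion list.

Identity is computed on a global (end-to-end) alignment since the exons
compared are full-length homologs; scores are match +1, mismatch -1, gap -2
(linear) unless overridden.  Local-alignment identity from a seeded search
tool will differ somewhat on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .locus_model import GeneFeature, ValidationError


@dataclass(frozen=True)
class IdentityMatrix:
    """Percent-identity matrices over exons and over concatenated genes.

    ``exon`` is indexed by ``"<feature_id>:<exon_index>"`` keys; ``gene`` by
    feature id (identity of concatenated exon sequences).  Both are
    symmetric with a 100.0 diagonal.
    """

    exon: pd.DataFrame
    gene: pd.DataFrame


@dataclass(frozen=True)
class ArtifactFlag:
    """One deletion-member exon diagnosed as a multimapping hazard."""

    feature_id: str
    exon_index: int
    reason: str  # high_identity | high_multimap | both
    identity: float
    multimap_fraction: float
    partner_feature: str


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity of an optimal global alignment of two sequences.

    identity = 100 * matches / aligned columns (matches + mismatches +
    gapped columns).  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be non-empty")
    aligner = _aligner(match, mismatch, gap)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def exon_identity_matrix(
    features: Sequence[GeneFeature],
    sequences: Mapping[str, str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> IdentityMatrix:
    """All-vs-all identity over the exons of the given (same-family) features.

    ``sequences`` maps ``"<feature_id>:<exon_index>"`` to the exon's
    nucleotide sequence; every exon of every feature must be resolvable.
    Also returns per-gene identity of concatenated exon sequences.
    """
    exon_keys: list[str] = []
    gene_seqs: dict[str, str] = {}
    for f in features:
        parts = []
        for i in range(len(f.exons)):
            key = f"{f.feature_id}:{i}"
            if key not in sequences:
                raise ValidationError(
                    f"missing sequence for {f.feature_id} exon {i}"
                )
            exon_keys.append(key)
            parts.append(sequences[key])
        gene_seqs[f.feature_id] = "".join(parts)

    def identity_frame(keys: list[str], seqs: Mapping[str, str]) -> pd.DataFrame:
        n = len(keys)
        mat = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                ident = pairwise_identity(
                    seqs[keys[i]], seqs[keys[j]], match, mismatch, gap
                )
                mat[i, j] = mat[j, i] = ident
        return pd.DataFrame(mat, index=keys, columns=keys)

    return IdentityMatrix(
        exon=identity_frame(exon_keys, sequences),
        gene=identity_frame(list(gene_seqs), gene_seqs),
    )


def flag_conserved_exons(
    identity_matrix: IdentityMatrix | None,
    depth_table: pd.DataFrame | None,
    features: Sequence[GeneFeature],
    identity_min: float = 95.0,
    multimap_min: float = 0.9,
) -> list[ArtifactFlag]:
    """Flag deletion-member exons prone to cross-paralog multimapping.

    An exon is flagged when its best identity to any exon of a retained
    same-family paralog reaches ``identity_min`` percent, or its
    cohort-median multimap fraction reaches ``multimap_min``.  Either input
    may be None to diagnose from one evidence source alone.
    """
    deleted = [f for f in features if f.role == "deletion_member"]
    retained = [f for f in features if f.role == "array_reference"]

    mm_median: dict[tuple[str, int], float] = {}
    if depth_table is not None and len(depth_table):
        exon_rows = depth_table[depth_table["exon_index"] != "ALL"]
        # one value per (sample, feature, exon); profiles share the fraction
        dedup = exon_rows.drop_duplicates(["sample_id", "feature_id", "exon_index"])
        grouped = dedup.groupby(["feature_id", "exon_index"])["multimap_fraction"].median()
        mm_median = {
            (fid, int(idx)): float(v) for (fid, idx), v in grouped.items()
        }

    flags: list[ArtifactFlag] = []
    for f in deleted:
        for i in range(len(f.exons)):
            best_identity = float("nan")
            best_partner = ""
            if identity_matrix is not None:
                key = f"{f.feature_id}:{i}"
                if key in identity_matrix.exon.index:
                    row = identity_matrix.exon.loc[key]
                    for partner in retained:
                        if partner.family != f.family:
                            continue
                        for j in range(len(partner.exons)):
                            pkey = f"{partner.feature_id}:{j}"
                            if pkey in row.index:
                                ident = float(row[pkey])
                                if math.isnan(best_identity) or ident > best_identity:
                                    best_identity = ident
                                    best_partner = partner.feature_id
            mm = mm_median.get((f.feature_id, i), float("nan"))

            high_identity = (
                not math.isnan(best_identity) and best_identity >= identity_min
            )
            high_multimap = not math.isnan(mm) and mm >= multimap_min
            if not (high_identity or high_multimap):
                continue
            reason = (
                "both" if high_identity and high_multimap
                else "high_identity" if high_identity
                else "high_multimap"
            )
            flags.append(
                ArtifactFlag(
                    feature_id=f.feature_id, exon_index=i, reason=reason,
                    identity=best_identity, multimap_fraction=mm,
                    partner_feature=best_partner,
                )
            )
    return flags


def flags_to_frame(flags: Sequence[ArtifactFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": fl.feature_id, "exon_index": fl.exon_index,
                "reason": fl.reason, "identity": fl.identity,
                "multimap_fraction": fl.multimap_fraction,
                "partner_feature": fl.partner_feature,
            }
        for fl in flags
        ],
        columns=[
            "feature_id", "exon_index", "reason", "identity",
            "multimap_fraction", "partner_feature",
        ],
    )


def identity_to_ambiguous_fraction(
    identity_pct: float, read_length: int = 100, mismatch_tolerance: float = 0.05
) -> float:
    """Heuristic share of reads expected to multimap between two paralogs.

    A read stays ambiguous when its mismatches against the partner paralog
    fall within the aligner's scoring margin, approximated as at most
    ``mismatch_tolerance * read_length`` mismatches with per-base divergence
    ``1 - identity/100``; the fraction is the binomial CDF at that cutoff.
    Monotone increasing in identity.
    """
    if not 0 <= identity_pct <= 100:
        raise ValidationError("identity must be in [0, 100]")
    divergence = 1.0 - identity_pct / 100.0
    cutoff = math.floor(mismatch_tolerance * read_length)
    return float(stats.binom.cdf(cutoff, read_length, divergence))
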