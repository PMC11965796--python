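"""Seeded synthetic diploid cohorts over a toy tandem gene array.

The generator emulates exon-capture sequencing depth over a ~20-gene tandem
toxin array in which a contiguous block of paralogs is deleted on one
haplotype, plus an unlinked multi-copy gene family (a myotoxin analog) on a
second chromosome whose diploid copy number varies per sample, plus a panel
of single-copy nontoxin reference genes.  Every downstream stage — coverage,
artifact flagging, deletion genotyping, copy-number estimation, association
testing — is testable against the returned ground truth without any external
data.

Model summary (full account in docs/methods.md):

* per exon base, expected depth is ``mean_depth * c / 2`` where ``c`` is the
  summed haplotype copy count (2 for HomoRef, 1 for Het, 0 for HomoDel over
  deletion members; the sample's diploid copy number for the copy-number
  target family);
* read counts per exon are Poisson or negative-binomial; reads have a fixed
  length and a uniform start within the exon;
* a configurable fraction of reads are flagged PCR duplicates;
* cross-mapping between a retained paralog and a conserved exon of a deleted
  paralog is modelled by emitting the source gene's copy-scaled signal onto
  the sink exon, with every read landing there multimapped (MAPQ 0) with
  probability ``ambiguous_fraction`` and spuriously unique otherwise;
* copy-number-target reads are multimapped at a high background rate, so a
  uniqueness filter systematically underestimates that family's dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import GeneFeature, ReadRecord, make_cohort_table

GENOTYPES = ("HomoRef", "Het", "HomoDel")


class ConfigError(ValueError):
    """A simulation configuration violates an invariant."""


@dataclass(frozen=True)
class CrossMapSpec:
    """Cross-mapping between a retained source gene and a sink gene's exons.

    ``ambiguous_fraction`` is the probability that a read landing on the sink
    exon is multimapped (MAPQ 0); the remainder are emitted as spuriously
    unique alignments, mirroring how a small share of reads from conserved
    paralog exons receive high MAPQ despite being ambiguous.
    """

    source_gene: str
    sink_gene: str
    exon_indices: tuple[int, ...]
    ambiguous_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ConfigError("ambiguous_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RegionSpec:
    """Samples drawn from one geographic region with its own genotype simplex."""

    n_samples: int
    genotype_freqs: tuple[float, float, float]  # (HomoRef, Het, HomoDel)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("region must contain at least one sample")
        if abs(sum(self.genotype_freqs) - 1.0) > 1e-9 or min(self.genotype_freqs) < 0:
            raise ConfigError("genotype frequencies must be a simplex summing to 1")


def _default_regions() -> dict[str, RegionSpec]:
    # Emulates a range-wide cohort: the deletion haplotype rare overall but
    # locally dominant at the northwestern periphery.
    return {
        "core": RegionSpec(n_samples=119, genotype_freqs=(0.97, 0.025, 0.005)),
        "northwest": RegionSpec(n_samples=20, genotype_freqs=(0.30, 0.15, 0.55)),
    }


#: Default conserved-exon pair: one deleted paralog shares near-identical
#: last exons with a retained paralog, so ~95% of reads on those exons are
#: multimapped.  Applied only when the array actually contains both genes.
_DEFAULT_SINK = 12
_DEFAULT_SOURCE = 17


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the target system: a 20-gene toxin array with genes
    11–16 deleted on one haplotype, capture depth ~30x for diploid
    single-copy targets, a myotoxin-analog family with per-sample diploid
    copy number uniform on {2..8} and independent of the array genotype,
    and 10 single-copy nontoxin reference genes on the same second
    chromosome as the copy-number target.
    """

    family: str = "SVMP"
    n_array_genes: int = 20
    deletion_span: tuple[int, int] = (11, 16)  # inclusive 1-based gene indices
    exons_per_gene: int = 3
    exon_length: int = 150
    intron_length: int = 350
    read_length: int = 100
    mean_depth: float = 30.0
    overdispersion: str = "poisson"  # or "negative_binomial"
    nb_size: float = 10.0
    dup_rate: float = 0.05
    cross_map: tuple[CrossMapSpec, ...] | None = None  # None -> default pair
    regions: Mapping[str, RegionSpec] = field(default_factory=_default_regions)
    cn_family: str = "MYO"
    cn_exons_per_gene: int = 4
    cn_target_exon_indices: tuple[int, ...] = (1, 2)  # exon 2 and exon 3
    cn_copies: int | tuple[int, int] = (2, 8)  # fixed, or inclusive uniform range
    cn_multimap_fraction: float = 0.8
    n_cn_reference_genes: int = 10
    conserved_identity: float = 97.5  # % identity of cross-mapped exon pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cross_map is None:
            lo, hi = self.deletion_span
            resolved: tuple[CrossMapSpec, ...] = ()
            if (
                lo <= _DEFAULT_SINK <= hi <= self.n_array_genes >= _DEFAULT_SOURCE
                and not lo <= _DEFAULT_SOURCE <= hi
                and self.exons_per_gene >= 3
            ):
                resolved = (
                    CrossMapSpec(
                        source_gene=self._array_gene_id(_DEFAULT_SOURCE),
                        sink_gene=self._array_gene_id(_DEFAULT_SINK),
                        exon_indices=(self.exons_per_gene - 2, self.exons_per_gene - 1),
                        ambiguous_fraction=0.95,
                    ),
                )
            object.__setattr__(self, "cross_map", resolved)

    def validate(self) -> None:
        if self.n_array_genes < 1:
            raise ConfigError("n_array_genes must be >= 1")
        lo, hi = self.deletion_span
        if lo > hi and not (lo == 1 and hi == 0):  # (1, 0) encodes an empty span
            raise ConfigError("deletion_span must be (low, high) with low <= high")
        if hi > self.n_array_genes or (lo < 1 and hi != 0):
            raise ConfigError("deletion_span outside the array")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if not 0.0 <= self.dup_rate < 0.5:
            raise ConfigError("dup_rate must be in [0, 0.5)")
        if self.overdispersion not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown overdispersion {self.overdispersion!r}")
        if self.read_length > self.exon_length:
            raise ConfigError("read_length must not exceed exon_length")
        if not self.regions:
            raise ConfigError("at least one region is required")
        for spec in self.regions.values():
            if not isinstance(spec, RegionSpec):
                raise ConfigError("regions must map names to RegionSpec")
        gene_ids = {self._array_gene_id(i) for i in range(1, self.n_array_genes + 1)}
        for cm in self.cross_map:
            if cm.sink_gene not in gene_ids or cm.source_gene not in gene_ids:
                raise ConfigError(
                    f"cross_map references unknown gene(s): {cm.source_gene}, {cm.sink_gene}"
                )
            for idx in cm.exon_indices:
                if not 0 <= idx < self.exons_per_gene:
                    raise ConfigError(f"cross_map exon index {idx} out of range")

    def _array_gene_id(self, i: int) -> str:
        return f"{self.family}-{i:02d}"

    @property
    def deletion_member_ids(self) -> tuple[str, ...]:
        lo, hi = self.deletion_span
        return tuple(self._array_gene_id(i) for i in range(lo, hi + 1))

    @property
    def chrom_sizes(self) -> dict[str, int]:
        gene_span = self.exons_per_gene * (self.exon_length + self.intron_length)
        return {
            "chrArray": (self.n_array_genes + 1) * gene_span,
            "chrCN": (self.n_cn_reference_genes + 3) * gene_span,
        }


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------


def build_toy_locus(
    config: SimulationConfig,
) -> tuple[list[GeneFeature], dict[str, tuple[int, int]]]:
    """Build the toy locus and the per-haplotype copy map.

    Returns the gene features (tandem-array genes with deletion members
    tagged, the copy-number target gene, and single-copy reference genes on a
    second chromosome) and a mapping ``feature_id -> (copies on the intact
    haplotype, copies on the deletion haplotype)``.  The copy-number target's
    dose is per-sample and therefore not part of this static map.
    """
    config.validate()
    gene_span = config.exons_per_gene * (config.exon_length + config.intron_length)
    deletion_ids = set(config.deletion_member_ids)

    def exons_at(offset: int, n_exons: int) -> tuple[tuple[int, int], ...]:
        return tuple(
            (
                offset + k * (config.exon_length + config.intron_length),
                offset + k * (config.exon_length + config.intron_length) + config.exon_length,
            )
            for k in range(n_exons)
        )

    features: list[GeneFeature] = []
    copy_map: dict[str, tuple[int, int]] = {}
    for i in range(1, config.n_array_genes + 1):
        fid = config._array_gene_id(i)
        role = "deletion_member" if fid in deletion_ids else "array_reference"
        features.append(
            GeneFeature(
                feature_id=fid, family=config.family, chrom="chrArray",
                strand="+", exons=exons_at((i - 1) * gene_span, config.exons_per_gene),
                role=role,
            )
        )
        copy_map[fid] = (1, 0) if fid in deletion_ids else (1, 1)

    cn_id = f"{config.cn_family}-01"
    features.append(
        GeneFeature(
            feature_id=cn_id, family=config.cn_family, chrom="chrCN",
            strand="+", exons=exons_at(0, config.cn_exons_per_gene),
            role="cn_target",
        )
    )
    copy_map[cn_id] = (1, 1)  # nominal; actual dose comes from truth rows

    for j in range(1, config.n_cn_reference_genes + 1):
        fid = f"NT-{j:02d}"
        features.append(
            GeneFeature(
                feature_id=fid, family="nontoxin", chrom="chrCN", strand="+",
                exons=exons_at((j + 1) * gene_span, config.exons_per_gene),
                role="cn_reference",
            )
        )
        copy_map[fid] = (1, 1)
    return features, copy_map


def cn_target_exons(
    features: Sequence[GeneFeature], indices: tuple[int, ...] = (1, 2)
) -> list[tuple[str, int]]:
    """Designated (feature_id, exon_index) pairs used for copy-number dosage."""
    out: list[tuple[str, int]] = []
    for f in features:
        if f.role == "cn_target":
            out.extend((f.feature_id, i) for i in indices if i < len(f.exons))
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _feature_copies(feature: GeneFeature, sv_genotype: str, copy_number: int) -> int:
    if feature.role == "deletion_member":
        return {"HomoRef": 2, "Het": 1, "HomoDel": 0}[sv_genotype]
    if feature.role == "cn_target":
        return copy_number
    return 2


def _draw_read_count(rng: np.random.Generator, mean: float, config: SimulationConfig) -> int:
    if mean <= 0:
        return 0
    if config.overdispersion == "poisson":
        return int(rng.poisson(mean))
    # negative binomial parameterised by mean and size (dispersion) k:
    # variance = mean + mean^2 / k
    k = config.nb_size
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def _emit_exon_reads(
    rng: np.random.Generator,
    sample_id: str,
    chrom: str,
    exon: tuple[int, int],
    expected_depth: float,
    multimap_prob: float,
    config: SimulationConfig,
    out: list[ReadRecord],
) -> None:
    start, end = exon
    exon_len = end - start
    read_len = min(config.read_length, exon_len)
    mean_reads = expected_depth * exon_len / read_len
    n = _draw_read_count(rng, mean_reads, config)
    if n == 0:
        return
    positions = rng.integers(start, end - read_len + 1, size=n)
    if multimap_prob > 0:
        mm = rng.random(n) < multimap_prob
    else:
        mm = np.zeros(n, dtype=bool)
    # PCR duplicates are extra copies of real reads so the duplicate-free
    # signal keeps its expected depth; overall duplicate share ~= dup_rate.
    if config.dup_rate > 0:
        n_dup = rng.binomial(n, config.dup_rate / (1.0 - config.dup_rate))
        dup_idx = rng.integers(0, n, size=n_dup)
    else:
        dup_idx = np.empty(0, dtype=int)
    for pos, is_mm in zip(positions.tolist(), mm.tolist()):
        out.append(
            ReadRecord(
                sample_id=sample_id, chrom=chrom, start=int(pos), length=read_len,
                mapq=0 if is_mm else 60, is_duplicate=False, is_multimapped=is_mm,
            )
        )
    base = len(out) - n  # start of this exon's freshly emitted block
    for idx in dup_idx.tolist():
        out.append(replace(out[base + idx], is_duplicate=True))


def simulate_sample_reads(
    features: Sequence[GeneFeature],
    truth_row: Mapping[str, object],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ReadRecord]:
    """Simulate one sample's aligned reads given its ground truth.

    ``truth_row`` must provide ``sample_id``, ``true_sv_genotype`` and
    ``true_copy_number``.
    """
    sample_id = str(truth_row["sample_id"])
    genotype = str(truth_row["true_sv_genotype"])
    copy_number = int(truth_row["true_copy_number"])
    if genotype not in GENOTYPES:
        raise ConfigError(f"unknown genotype {genotype!r}")

    by_id = {f.feature_id: f for f in features}
    # sink exon -> summed extra source signal and its ambiguous fraction
    cross: dict[tuple[str, int], tuple[float, float]] = {}
    for cm in config.cross_map:
        source = by_id.get(cm.source_gene)
        if source is None:
            continue
        c_src = _feature_copies(source, genotype, copy_number)
        extra = config.mean_depth * c_src / 2.0
        for idx in cm.exon_indices:
            prev_extra, _ = cross.get((cm.sink_gene, idx), (0.0, 0.0))
            cross[(cm.sink_gene, idx)] = (prev_extra + extra, cm.ambiguous_fraction)

    reads: list[ReadRecord] = []
    for feature in features:
        copies = _feature_copies(feature, genotype, copy_number)
        own_depth = config.mean_depth * copies / 2.0
        base_mm = config.cn_multimap_fraction if feature.role == "cn_target" else 0.0
        for i, exon in enumerate(feature.exons):
            extra_depth, ambiguous = cross.get((feature.feature_id, i), (0.0, 0.0))
            depth = own_depth + extra_depth
            mm_prob = ambiguous if extra_depth > 0 else base_mm
            _emit_exon_reads(
                rng, sample_id, feature.chrom, exon, depth, mm_prob, config, reads
            )
    return reads


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Simulate a full cohort; deterministic given (config, seed).

    A single root seed drives everything; per-sample substreams are spawned
    by counter so the same sample always receives the same reads regardless
    of generation order.
    """
    config.validate()
    root_seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(root_seed)
    n_total = sum(spec.n_samples for spec in config.regions.values())
    streams = root.spawn(n_total + 1)
    rng_cohort = np.random.default_rng(streams[0])

    features, _ = build_toy_locus(config)
    truth_rows: list[dict[str, object]] = []
    idx = 0
    for region_name in config.regions:
        spec = config.regions[region_name]
        genotypes = rng_cohort.choice(
            GENOTYPES, size=spec.n_samples, p=list(spec.genotype_freqs)
        )
        for g in genotypes:
            if isinstance(config.cn_copies, tuple):
                lo, hi = config.cn_copies
                cn = int(rng_cohort.integers(lo, hi + 1))
            else:
                cn = int(config.cn_copies)
            truth_rows.append(
                {
                    "sample_id": f"S{idx:04d}",
                    "region_label": region_name,
                    "true_sv_genotype": str(g),
                    "true_copy_number": cn,
                    "seed": root_seed,
                }
            )
            idx += 1

    reads_by_sample: dict[str, list[ReadRecord]] = {}
    for i, row in enumerate(truth_rows):
        rng = np.random.default_rng(streams[i + 1])
        reads_by_sample[row["sample_id"]] = simulate_sample_reads(
            features, row, config, rng
        )
    truth = make_cohort_table(truth_rows)
    truth["seed"] = root_seed
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# exon sequences (for identity-based artifact diagnosis)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_exon_sequences(
    features: Sequence[GeneFeature],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, str]:
    """Generate per-exon nucleotide sequences keyed ``"<feature_id>:<exon>"``.

    Exons are independent random sequences except cross-mapped sink exons,
    which are copies of their source exon mutated at a per-base rate of
    ``(100 - conserved_identity) / 100`` — so the sink/source pair's global
    alignment identity concentrates around ``conserved_identity`` percent
    while unrelated exon pairs sit far below any conservation threshold.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed if seed is None else seed) + 2**20)
    )
    seqs: dict[str, str] = {}
    for f in features:
        for i, (s, e) in enumerate(f.exons):
            seqs[f"{f.feature_id}:{i}"] = "".join(
                rng.choice(_BASES, size=e - s).tolist()
            )
    rate = (100.0 - config.conserved_identity) / 100.0
    for cm in config.cross_map:
        for idx in cm.exon_indices:
            src_key = f"{cm.source_gene}:{idx}"
            sink_key = f"{cm.sink_gene}:{idx}"
            if src_key not in seqs or sink_key not in seqs:
                continue
            src = np.array(list(seqs[src_key]))
            mutate = rng.random(src.size) < rate
            if mutate.any():
                # substitute with a uniformly chosen *different* base
                offsets = rng.integers(1, 4, size=int(mutate.sum()))
                base_idx = np.searchsorted(_BASES, src[mutate])
                src[mutate] = _BASES[(base_idx + offsets) % 4]
            seqs[sink_key] = "".join(src.tolist())
    return seqs
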