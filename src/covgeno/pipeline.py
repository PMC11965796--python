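"""End-to-end orchestration of the synthetic analysis.

Runs the staged analysis ``simulate -> coverage -> flag-artifacts ->
genotype-sv -> copy-number -> assoc`` from a single config and seed,
writing every intermediate as a commented-metadata TSV so stages are
human-diffable, individually re-runnable, and byte-identical across
repeated runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from . import __version__
from .assoc_stats import association_to_frame, frequency_summary, genotype_cn_association
from .copy_number import copy_number_cohort
from .feature_coverage import build_depth_table
from .locus_model import (
    ALL_PROFILE,
    PROFILES,
    UNIQUE_PROFILE,
    read_alignments,
    read_fasta,
    read_features,
    read_table,
    write_alignments_sam,
    write_fasta,
    write_features,
    write_table,
)
from .paralog_artifacts import exon_identity_matrix, flag_conserved_exons, flags_to_frame
from .sv_genotyper import GenotypeThresholds, calls_to_frame, genotype_cohort
from .synthetic_cohort import (
    CrossMapSpec,
    RegionSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_exon_sequences,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "coverage", "flag_artifacts", "genotype_sv", "copy_number",
    "assoc",
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML/JSON.

    In simulate mode (``simulate=True``) inputs are generated from
    ``simulation``; otherwise ``features_path``/``alignments_path`` (and
    optionally ``fasta_path``, ``cohort_path``) must point at existing
    files.
    """

    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    features_path: str | None = None
    alignments_path: str | None = None
    fasta_path: str | None = None
    cohort_path: str | None = None
    thresholds: GenotypeThresholds = field(default_factory=GenotypeThresholds)
    identity_min: float = 95.0
    multimap_min: float = 0.9
    genotype_profile: str = "unique"
    cn_profile: str = "all"
    cn_target_exon_indices: tuple[int, ...] = (1, 2)
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (or JSON, a YAML subset)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    sim_raw = raw.pop("simulation", {})
    if "regions" in sim_raw:
        sim_raw["regions"] = {
            name: RegionSpec(
                n_samples=int(spec["n_samples"]),
                genotype_freqs=tuple(spec["genotype_freqs"]),
            )
            for name, spec in sim_raw["regions"].items()
        }
    if "cross_map" in sim_raw:
        sim_raw["cross_map"] = tuple(
            CrossMapSpec(
                source_gene=cm["source_gene"], sink_gene=cm["sink_gene"],
                exon_indices=tuple(cm["exon_indices"]),
                ambiguous_fraction=float(cm["ambiguous_fraction"]),
            )
            for cm in sim_raw["cross_map"]
        )
    for key in ("deletion_span", "cn_target_exon_indices", "cn_copies"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    thr_raw = raw.pop("thresholds", {})
    if "cn_target_exon_indices" in raw and isinstance(raw["cn_target_exon_indices"], list):
        raw["cn_target_exon_indices"] = tuple(raw["cn_target_exon_indices"])
    return PipelineConfig(
        simulation=SimulationConfig(**sim_raw),
        thresholds=GenotypeThresholds(**thr_raw),
        **raw,
    )


def validate_config(config: PipelineConfig) -> list[str]:
    """Check threshold orderings, profiles and referenced paths.

    Returns a list of human-readable violations (empty when valid), each
    prefixed with the offending field path.
    """
    issues: list[str] = []
    t = config.thresholds
    if not 0 < t.homodel_max < t.het_low < t.het_high < t.homoref_min:
        issues.append(
            "thresholds: require 0 < homodel_max < het_low < het_high < homoref_min"
        )
    if not 0 <= config.identity_min <= 100:
        issues.append("identity_min: must be in [0, 100]")
    if not 0 <= config.multimap_min <= 1:
        issues.append("multimap_min: must be in [0, 1]")
    for name in (config.genotype_profile, config.cn_profile):
        if name not in PROFILES:
            issues.append(f"profile {name!r}: unknown (choose from {sorted(PROFILES)})")
    if config.simulate:
        try:
            config.simulation.validate()
        except ValueError as exc:
            issues.append(f"simulation: {exc}")
    else:
        for attr in ("features_path", "alignments_path"):
            value = getattr(config, attr)
            if value is None:
                issues.append(f"{attr}: required when simulate is false")
            elif not Path(value).exists():
                issues.append(f"{attr}: {value} does not exist")
        for attr in ("fasta_path", "cohort_path"):
            value = getattr(config, attr)
            if value is not None and not Path(value).exists():
                issues.append(f"{attr}: {value} does not exist")
        if config.fasta_path is None:
            issues.append(
                "fasta_path: required for the artifact-flagging stage "
                "(no identity evidence without sequences)"
            )
    return issues


def _metadata(config: PipelineConfig, stage: str) -> dict[str, object]:
    t = config.thresholds
    return {
        "covgeno_version": __version__,
        "stage": stage,
        "seed": config.seed,
        "homodel_max": t.homodel_max,
        "het_low": t.het_low,
        "het_high": t.het_high,
        "homoref_min": t.homoref_min,
        "identity_min": config.identity_min,
        "multimap_min": config.multimap_min,
        "genotype_profile": config.genotype_profile,
        "cn_profile": config.cn_profile,
    }


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the output directory.

    Deterministic given (config, seed): outputs carry no timestamps, and
    all randomness flows from ``config.seed``.  A failing stage raises with
    the stage name; outputs of completed stages are retained.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "covgeno_version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": [],
    }

    stage = "simulate"
    try:
        if config.simulate:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            reads_by_sample, truth = simulate_cohort(sim)
            from .synthetic_cohort import build_toy_locus

            features, _ = build_toy_locus(sim)
            sequences = simulate_exon_sequences(features, sim)
            write_features(features, out / "features.bed")
            write_alignments_sam(
                reads_by_sample, out / "alignments.sam", sim.chrom_sizes
            )
            write_fasta(sequences, out / "sequences.fasta")
            write_table(truth, out / "cohort.tsv", _metadata(config, stage))
            cohort = truth
            n_reads = sum(len(v) for v in reads_by_sample.values())
            logger.info("simulate: %d samples in, %d reads out", len(truth), n_reads)
            manifest["stages"].append({"stage": stage, "rows_out": n_reads})
        else:
            features = read_features(config.features_path)
            reads_by_sample = {}
            for r in read_alignments(config.alignments_path):
                reads_by_sample.setdefault(r.sample_id, []).append(r)
            sequences = read_fasta(config.fasta_path) if config.fasta_path else {}
            if config.cohort_path:
                cohort, _ = read_table(config.cohort_path)
            else:
                cohort = None
            n_reads = sum(len(v) for v in reads_by_sample.values())
            logger.info("load: %d samples, %d reads", len(reads_by_sample), n_reads)
            manifest["stages"].append({"stage": stage, "rows_out": n_reads})

        stage = "coverage"
        depth = build_depth_table(
            reads_by_sample, features, (UNIQUE_PROFILE, ALL_PROFILE), per_exon=True
        )
        write_table(depth, out / "depth.tsv", _metadata(config, stage))
        logger.info("coverage: %d reads in, %d depth rows out", n_reads, len(depth))
        manifest["stages"].append({"stage": stage, "rows_out": len(depth)})

        stage = "flag_artifacts"
        family_features = [
            f for f in features if f.role in ("deletion_member", "array_reference")
        ]
        identity = (
            exon_identity_matrix(family_features, sequences) if sequences else None
        )
        flags = flag_conserved_exons(
            identity, depth, features,
            identity_min=config.identity_min, multimap_min=config.multimap_min,
        )
        flags_df = flags_to_frame(flags)
        write_table(flags_df, out / "artifact_flags.tsv", _metadata(config, stage))
        logger.info(
            "flag_artifacts: %d depth rows in, %d flags out", len(depth), len(flags)
        )
        manifest["stages"].append({"stage": stage, "rows_out": len(flags)})

        stage = "genotype_sv"
        calls, summary = genotype_cohort(
            depth, features, config.thresholds, flags, cohort,
            profile=config.genotype_profile,
        )
        calls_df = calls_to_frame(calls)
        write_table(calls_df, out / "sv_calls.tsv", _metadata(config, stage))
        write_table(summary, out / "sv_counts.tsv", _metadata(config, stage))
        logger.info(
            "genotype_sv: %d depth rows in, %d calls out", len(depth), len(calls_df)
        )
        manifest["stages"].append({"stage": stage, "rows_out": len(calls_df)})

        stage = "copy_number"
        cn = copy_number_cohort(
            depth, features, cohort, calls_df,
            target_exon_indices=config.cn_target_exon_indices,
            profile=config.cn_profile,
        )
        write_table(cn, out / "copy_number.tsv", _metadata(config, stage))
        logger.info("copy_number: %d estimates out", len(cn))
        manifest["stages"].append({"stage": stage, "rows_out": len(cn)})

        stage = "assoc"
        assoc = association_to_frame(genotype_cn_association(calls_df, cn))
        freq = frequency_summary(calls_df, cohort)
        write_table(assoc, out / "association.tsv", _metadata(config, stage))
        write_table(freq, out / "frequencies.tsv", _metadata(config, stage))
        logger.info("assoc: %d tests, %d frequency rows", len(assoc), len(freq))
        manifest["stages"].append({"stage": stage, "rows_out": len(assoc) + len(freq)})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out
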