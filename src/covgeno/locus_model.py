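"""Genomic data model and standard-format I/O.

This module houses the shared domain types — exon-resolved gene models with a
functional role tag, aligned-read records, mapping-filter profiles, and cohort
metadata tables — together with readers and writers for the formats the
pipeline exchanges with the outside world: BED (3/6/12 columns, blocks as
exons, plus two appended columns carrying gene family and role), GFF3 (exon
children grouped by ``Parent``), SAM (via pysam), tab-separated read tables,
FASTA, and generic TSV outputs.

Coordinates are 0-based half-open everywhere internally; GFF3's 1-based closed
convention is converted at the boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Recognised functional roles of a gene feature within the analysis.
ROLES = frozenset(
    {"deletion_member", "array_reference", "cn_target", "cn_reference", "other"}
)

#: MAPQ below which a read is considered multimapped (short-read aligner
#: convention: near-equal alternative placements yield low mapping quality).
MULTIMAP_MAPQ = 30


class ParseError(ValueError):
    """A standard-format file could not be parsed; names the offending line."""


class ValidationError(ValueError):
    """An in-memory object violates a model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """An exon-resolved gene model with a role tag.

    Exons are 0-based half-open intervals, sorted and pairwise disjoint.
    Strand is stored but ignored by coverage computations (capture depth is
    strand-agnostic).
    """

    feature_id: str
    family: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    role: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.feature_id}: strand must be '+' or '-'")
        if self.role not in ROLES:
            raise ValidationError(f"{self.feature_id}: unknown role {self.role!r}")
        if not self.exons:
            raise ValidationError(f"{self.feature_id}: feature has no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s or s < 0:
                raise ValidationError(
                    f"{self.feature_id}: invalid exon interval [{s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"{self.feature_id}: exons overlap or are unsorted at [{s}, {e})"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        """Total exonic bases."""
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read, reduced to what depth computation consumes.

    ``length`` is the reference span of the alignment (CIGAR-aware when read
    from SAM).  ``is_multimapped`` is true when MAPQ falls below the
    uniqueness cutoff or the record carried a secondary/supplementary flag.
    """

    sample_id: str
    chrom: str
    start: int
    length: int
    mapq: int
    is_duplicate: bool = False
    is_multimapped: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"read start {self.start} < 0")
        if self.length < 1:
            raise ValidationError(f"read length {self.length} < 1")
        if not 0 <= self.mapq <= 60:
            raise ValidationError(f"MAPQ {self.mapq} outside [0, 60]")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class FilterProfile:
    """A named mapping-filter contract applied before depth computation."""

    profile_name: str
    mapq_min: int
    drop_duplicates: bool
    keep_multimapped: bool


#: Uniquely-mapped reads only: MAPQ >= 30, duplicates and multimappers dropped.
#: This is the profile used for deletion genotyping.
UNIQUE_PROFILE = FilterProfile(
    profile_name="unique", mapq_min=MULTIMAP_MAPQ, drop_duplicates=True,
    keep_multimapped=False,
)

#: Keep multimapped reads (duplicates still dropped) — required when
#: quantifying high-identity gene families whose reads cannot map uniquely.
ALL_PROFILE = FilterProfile(
    profile_name="all", mapq_min=0, drop_duplicates=True, keep_multimapped=True,
)

PROFILES: dict[str, FilterProfile] = {
    UNIQUE_PROFILE.profile_name: UNIQUE_PROFILE,
    ALL_PROFILE.profile_name: ALL_PROFILE,
}


COHORT_COLUMNS = ["sample_id", "region_label", "true_sv_genotype", "true_copy_number"]


def make_cohort_table(rows: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Build a cohort metadata table and enforce sample-id uniqueness."""
    df = pd.DataFrame(list(rows))
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[COHORT_COLUMNS]
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in cohort: {dupes}")
    return df


# ---------------------------------------------------------------------------
# feature I/O
# ---------------------------------------------------------------------------


def _sniff_feature_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "GFF3"
    return "BED"


def read_features(path: str | Path, format: str | None = None) -> list[GeneFeature]:
    """Read gene features from BED or GFF3.

    BED dialect: 3, 6 or 12 standard columns; with 12 columns the blocks
    become exons.  Two optional appended columns carry ``family`` and
    ``role``.  GFF3 dialect: ``gene`` records with ``ID``/``family``/``role``
    attributes and ``exon`` children grouped by ``Parent``; 1-based closed
    coordinates are converted to 0-based half-open.
    """
    fmt = (format or _sniff_feature_format(path)).upper()
    if fmt == "BED":
        return _read_bed(path)
    if fmt == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown feature format {format!r}")


def _read_bed(path: str | Path) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom = cols[0]
                start, end = int(cols[1]), int(cols[2])
                name = cols[3] if len(cols) > 3 else f"feature_{lineno}"
                strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
                if len(cols) >= 12:
                    n_blocks = int(cols[9])
                    sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
                    if len(sizes) != n_blocks or len(offsets) != n_blocks:
                        raise ValueError("blockCount disagrees with block lists")
                    exons = tuple(
                        (start + off, start + off + size)
                        for off, size in zip(offsets, sizes)
                    )
                    extra = cols[12:]
                else:
                    exons = ((start, end),)
                    extra = cols[6:] if len(cols) > 6 else []
                family = extra[0] if len(extra) > 0 and extra[0] else ""
                role = extra[1] if len(extra) > 1 and extra[1] else "other"
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                features.append(
                    GeneFeature(
                        feature_id=name, family=family, chrom=chrom,
                        strand=strand, exons=exons, role=role,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return features


def _read_gff3(path: str | Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = tuple(
            sorted((child.start - 1, child.end) for child in db.children(gene, featuretype="exon"))
        )
        if not exons:
            # a gene with no exon children is its own single exon
            exons = ((gene.start - 1, gene.end),)
        family = gene.attributes.get("family", [""])[0]
        role = gene.attributes.get("role", ["other"])[0]
        features.append(
            GeneFeature(
                feature_id=gene.id, family=family, chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons, role=role,
            )
        )
    return features


def write_features(
    features: Sequence[GeneFeature], path: str | Path, format: str | None = None
) -> None:
    """Write features as BED12+2 (family, role) or GFF3."""
    fmt = (format or _sniff_feature_format(path)).upper()
    if fmt == "BED":
        with open(path, "w") as handle:
            for f in features:
                start, end = f.start, f.end
                sizes = ",".join(str(e - s) for s, e in f.exons)
                offsets = ",".join(str(s - start) for s, e in f.exons)
                handle.write(
                    "\t".join(
                        [
                            f.chrom, str(start), str(end), f.feature_id, "0",
                            f.strand, str(start), str(end), "0",
                            str(len(f.exons)), sizes, offsets, f.family, f.role,
                        ]
                    )
                    + "\n"
                )
    elif fmt == "GFF3":
        with open(path, "w") as handle:
            handle.write("##gff-version 3\n")
            for f in features:
                attrs = f"ID={f.feature_id};family={f.family};role={f.role}"
                handle.write(
                    "\t".join(
                        [f.chrom, "covgeno", "gene", str(f.start + 1), str(f.end),
                         ".", f.strand, ".", attrs]
                    )
                    + "\n"
                )
                for i, (s, e) in enumerate(f.exons):
                    handle.write(
                        "\t".join(
                            [f.chrom, "covgeno", "exon", str(s + 1), str(e), ".",
                             f.strand, ".",
                             f"ID={f.feature_id}.exon{i};Parent={f.feature_id}"]
                        )
                        + "\n"
                    )
    else:
        raise ValueError(f"unknown feature format {format!r}")


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

READ_TSV_COLUMNS = [
    "sample_id", "chrom", "start", "length", "mapq", "is_duplicate",
    "is_multimapped",
]


def _sniff_alignment_format(path: str | Path) -> str:
    return "SAM" if Path(path).suffix.lower() == ".sam" else "TSV"


def read_alignments(
    path: str | Path, format: str | None = None, sample_id: str | None = None
) -> Iterator[ReadRecord]:
    """Stream aligned reads from SAM or a tabular read file.

    For SAM, the sample id comes from the read group's ``SM`` field when
    present, falling back to ``sample_id`` or the file stem.  Unmapped,
    secondary-only artifacts of parsing are skipped with a counted warning.
    """
    fmt = (format or _sniff_alignment_format(path)).upper()
    if fmt == "SAM":
        yield from _read_sam(path, sample_id)
    elif fmt == "TSV":
        yield from _read_read_tsv(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def _read_sam(path: str | Path, sample_id: str | None) -> Iterator[ReadRecord]:
    default_sample = sample_id or Path(path).stem
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        rg_to_sample = {
            rg.get("ID"): rg.get("SM", rg.get("ID"))
            for rg in sam.header.to_dict().get("RG", [])
        }
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                n_unmapped += 1
                continue
            length = rec.reference_length or rec.query_length or 0
            if length < 1:
                n_unmapped += 1
                continue
            sample = default_sample
            if rec.has_tag("RG"):
                sample = rg_to_sample.get(rec.get_tag("RG"), default_sample)
            multimapped = (
                rec.mapping_quality < MULTIMAP_MAPQ
                or rec.is_secondary
                or rec.is_supplementary
            )
            yield ReadRecord(
                sample_id=sample,
                chrom=rec.reference_name,
                start=rec.reference_start,
                length=length,
                mapq=min(rec.mapping_quality, 60),
                is_duplicate=rec.is_duplicate,
                is_multimapped=multimapped,
            )
    if n_unmapped:
        logger.warning("%s: skipped %d unmapped records", path, n_unmapped)


def _read_read_tsv(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[:2] == ["sample_id", "chrom"]:
                continue  # header
            if len(cols) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                yield ReadRecord(
                    sample_id=cols[0], chrom=cols[1], start=int(cols[2]),
                    length=int(cols[3]), mapq=int(cols[4]),
                    is_duplicate=bool(int(cols[5])),
                    is_multimapped=bool(int(cols[6])),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def write_alignments_tsv(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(READ_TSV_COLUMNS) + "\n")
        for r in reads:
            handle.write(
                f"{r.sample_id}\t{r.chrom}\t{r.start}\t{r.length}\t{r.mapq}\t"
                f"{int(r.is_duplicate)}\t{int(r.is_multimapped)}\n"
            )


def write_alignments_sam(
    reads_by_sample: Mapping[str, Sequence[ReadRecord]],
    path: str | Path,
    chrom_sizes: Mapping[str, int],
) -> None:
    """Write reads as a single text SAM with one read group per sample.

    Only the fields depth computation consumes are meaningful: position,
    MAPQ, duplicate flag (0x400) and a CIGAR encoding the reference span.
    Sequences are omitted ('*').  Output is deterministic for a fixed input.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": size} for name, size in chrom_sizes.items()],
        "RG": [{"ID": s, "SM": s} for s in reads_by_sample],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(chrom_sizes)}
        for sample in reads_by_sample:
            for i, r in enumerate(reads_by_sample[sample]):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{sample}.{i}"
                a.reference_id = tid[r.chrom]
                a.reference_start = r.start
                a.mapping_quality = r.mapq
                a.cigarstring = f"{r.length}M"
                a.flag = 0x400 if r.is_duplicate else 0
                a.set_tag("RG", sample)
                out.write(a)


# ---------------------------------------------------------------------------
# FASTA and generic tables
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_table(
    rows: pd.DataFrame | Sequence[Mapping[str, object]],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV with an optional ``#key=value`` metadata header.

    Rows are sorted deterministically (by sample then feature when those
    columns exist, otherwise by all columns) so repeated runs are
    byte-identical.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    sort_cols = [c for c in ("sample_id", "feature_id", "exon_index", "profile_name")
                 if c in df.columns]
    if not sort_cols:
        sort_cols = list(df.columns)
    if len(df) and sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    buf = io.StringIO()
    if metadata:
        for key, value in metadata.items():
            buf.write(f"#{key}={value}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as handle:
        handle.write(buf.getvalue())


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_table`; returns (frame, metadata)."""
    metadata: dict[str, str] = {}
    with open(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            metadata[key] = value
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        df = pd.read_csv(handle, sep="\t", dtype={"sample_id": str, "exon_index": str})
    return df, metadata
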