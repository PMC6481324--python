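"""Shared domain types, file formats, configuration, and logging.

Internal coordinates are 0-based half-open throughout; 1-based formats
(VCF) are converted at the I/O boundary so interval arithmetic is uniform
across stages. All serialized domain objects are plain dataclasses that
validate their invariants on construction.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from oncopanel.errors import FormatError, ParameterError

CONSEQUENCES = (
    "missense",
    "nonsense",
    "stop_loss",
    "frameshift_indel",
    "inframe_indel",
    "synonymous",
    "noncoding",
)
ORIGINS = ("somatic", "germline")
STRANDS = ("+", "-", ".")


def get_logger(stage: str) -> logging.Logger:
    """Structured stderr logger named for a pipeline stage."""
    logger = logging.getLogger(f"oncopanel.{stage}")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.propagate = False
    return logger


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded). Conversion to and
    from 1-based closed coordinates is lossless for intervals of length
    at least one.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ParameterError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ParameterError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_1based(self) -> tuple[str, int, int]:
        """(chrom, first base, last base) in 1-based closed coordinates."""
        return (self.chrom, self.start + 1, self.end)

    @classmethod
    def from_1based(
        cls, chrom: str, first: int, last: int, strand: str = "."
    ) -> "GenomicInterval":
        return cls(chrom, first - 1, last, strand)


@dataclass(frozen=True)
class VariantRecord:
    """One small somatic or germline variant with its read evidence.

    ``vaf`` is the variant allele fraction as given in the input; the
    toolkit never re-derives it from alignments. ``consequence`` is one
    of :data:`CONSEQUENCES`, pre-annotated upstream.
    """

    interval: GenomicInterval
    ref_allele: str
    alt_allele: str
    vaf: float
    depth: int
    consequence: str
    origin: str = "somatic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ParameterError(f"VAF {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ParameterError(f"negative depth {self.depth}")
        if self.ref_allele == self.alt_allele:
            raise ParameterError("ref and alt alleles identical")
        if self.consequence not in CONSEQUENCES:
            raise ParameterError(f"unknown consequence {self.consequence!r}")
        if self.origin not in ORIGINS:
            raise ParameterError(f"unknown origin {self.origin!r}")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS bounds of one (canonical) transcript.

    Exons are stored sorted by genomic position regardless of strand;
    transcription order for minus-strand transcripts is the reverse.
    ``exon_sequences``, when present, hold the genomic-forward-strand
    nucleotide sequence of each exon and align with ``exons``.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int
    promoter: GenomicInterval | None = None
    protein_id: str | None = None
    exon_sequences: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParameterError(f"transcript strand must be +/-, got {self.strand!r}")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ParameterError(f"{self.transcript_id}: no exons")
        for a, b in zip(exons, exons[1:]):
            if a.chrom != b.chrom:
                raise ParameterError(f"{self.transcript_id}: exons on two chromosomes")
            if b.start < a.end:
                raise ParameterError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        if not self.cds_start < self.cds_end:
            raise ParameterError(f"{self.transcript_id}: empty CDS")
        for bound in (self.cds_start, self.cds_end - 1):
            if not any(e.contains(bound) for e in exons):
                raise ParameterError(
                    f"{self.transcript_id}: CDS bound {bound} outside exon union"
                )
        if self.exon_sequences is not None:
            seqs = tuple(self.exon_sequences)
            object.__setattr__(self, "exon_sequences", seqs)
            if len(seqs) != len(exons):
                raise ParameterError(
                    f"{self.transcript_id}: {len(seqs)} sequences for "
                    f"{len(exons)} exons"
                )
            for e, s in zip(exons, seqs):
                if len(s) != e.length:
                    raise ParameterError(
                        f"{self.transcript_id}: sequence length {len(s)} != "
                        f"exon length {e.length}"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def tx_start(self) -> int:
        """Transcriptional start coordinate (strand aware)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    def exon_order(self) -> list[int]:
        """Indices into ``exons`` in transcription order (0-based)."""
        idx = list(range(len(self.exons)))
        return idx if self.strand == "+" else idx[::-1]


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein functional domain in 1-based amino-acid coordinates."""

    protein_id: str
    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ParameterError(
                f"domain {self.name}: bad bounds {self.aa_start}-{self.aa_end}"
            )


@dataclass(frozen=True)
class MicrosatelliteLocusProfile:
    """Tumor (and optionally normal) repeat-length read histograms at one locus.

    The unit of evidence for MSI calling: a map repeat-length -> read count
    per sample, restricted upstream to reads spanning the repeat with
    sufficient flanking sequence (``flank_ok``).
    """

    locus_id: str
    repeat_unit: str
    ref_repeats: int
    tumor_hist: Mapping[int, int]
    normal_hist: Mapping[int, int] | None = None
    flank_ok: bool = True

    def __post_init__(self) -> None:
        for name, hist in (("tumor", self.tumor_hist), ("normal", self.normal_hist)):
            if hist is None:
                continue
            if any(c < 0 for c in hist.values()):
                raise ParameterError(f"{self.locus_id}: negative {name} read count")

    @property
    def tumor_reads(self) -> int:
        return int(sum(self.tumor_hist.values()))

    @property
    def normal_reads(self) -> int:
        return 0 if self.normal_hist is None else int(sum(self.normal_hist.values()))


@dataclass(frozen=True)
class TargetCoverage:
    """Read depth over one capture target in tumor and matched normal."""

    interval: GenomicInterval
    gene: str
    tumor_depth: float
    normal_depth: float
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ParameterError(f"{self.gene}: negative depth")
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise ParameterError(f"{self.gene}: GC fraction outside [0, 1]")


@dataclass(frozen=True)
class HetSnvObservation:
    """Tumor allele fraction of a heterozygous germline SNV."""

    interval: GenomicInterval
    tumor_alt_fraction: float
    tumor_depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_alt_fraction <= 1.0:
            raise ParameterError("alt fraction outside [0, 1]")
        if self.tumor_depth <= 0:
            raise ParameterError("het-SNV depth must be positive")


SV_CLASSES = ("deletion", "inversion", "duplication", "translocation")


@dataclass(frozen=True)
class SvCandidate:
    """A structural-variant candidate: two breakpoint ends plus read support."""

    end_a: GenomicInterval
    end_b: GenomicInterval
    name: str
    split_reads: int
    discordant_reads: int
    sv_class: str

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.discordant_reads < 0:
            raise ParameterError(f"{self.name}: negative read support")
        if self.sv_class not in SV_CLASSES:
            raise ParameterError(f"unknown SV class {self.sv_class!r}")


@dataclass
class AssayConfig:
    """Every scalar threshold of the assay, with its clinical default.

    Defaults follow the validated assay configuration: a 2.4 Mb panel,
    TMB-high above 9 mutations/Mb, 30-read microsatellite locus coverage
    with 20 of 43 loci required, 30/70% MSI probability bands, a 2.5
    copy-ratio amplification boundary, a 500 nM neoantigen affinity
    cutoff over 8-11-mer peptides, and 95% of targeted bases at 300x
    for coverage uniformity. All values are overridable from a flat
    YAML/JSON document.
    """

    panel_megabases: float = 2.4
    tmb_high_threshold: float = 9.0
    tmb_min_depth: int = 100
    tmb_min_vaf: float = 0.05
    msi_min_locus_reads: int = 30
    msi_min_loci: int = 20
    msi_flank_bp: int = 5
    msi_locus_p_cutoff: float = 0.05
    msi_prob_low: float = 0.30
    msi_prob_high: float = 0.70
    amplification_ratio: float = 2.5
    affinity_cutoff_nm: float = 500.0
    peptide_min_length: int = 8
    peptide_max_length: int = 11
    fusion_min_support: int = 5
    uniformity_depth: int = 300
    uniformity_fraction: float = 0.95
    cbs_alpha: float = 0.01
    cbs_n_permutations: int = 10_000
    cbs_merge_tolerance: float = 0.1
    arm_event_fraction: float = 0.80
    expression_percentile: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "panel_megabases",
            "tmb_high_threshold",
            "tmb_min_depth",
            "msi_min_locus_reads",
            "msi_min_loci",
            "msi_flank_bp",
            "msi_locus_p_cutoff",
            "amplification_ratio",
            "affinity_cutoff_nm",
            "peptide_min_length",
            "peptide_max_length",
            "uniformity_depth",
            "uniformity_fraction",
            "cbs_alpha",
            "cbs_n_permutations",
            "arm_event_fraction",
            "expression_percentile",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not self.msi_prob_low < self.msi_prob_high:
            raise ParameterError("msi_prob_low must be below msi_prob_high")
        if self.peptide_min_length > self.peptide_max_length:
            raise ParameterError("peptide length range is empty")

    @classmethod
    def from_file(cls, path: str) -> "AssayConfig":
        """Load overrides from a flat YAML or JSON key-value document."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise FormatError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def override(self, **kwargs) -> "AssayConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Variant tables (VCF 4.2 subset / TSV dialect)
# ---------------------------------------------------------------------------

_VCF_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")
_TSV_COLUMNS = (
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "vaf",
    "depth",
    "consequence",
    "origin",
)


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in info.split(";"):
        if not item or item == ".":
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def read_variant_table(path: str, dialect: str = "vcf") -> list[VariantRecord]:
    """Read variants from a VCF 4.2 subset or the named-column TSV dialect.

    VAF and depth come from single designated fields (``AF``/``DP`` in the
    VCF INFO column; ``vaf``/``depth`` TSV columns) and are never
    recomputed. VCF positions are 1-based and converted to the internal
    0-based half-open convention; the variant interval spans the
    reference allele.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    raise ParameterError(f"unknown dialect {dialect!r}")


def _read_vcf(path: str) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                saw_header = True
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise FormatError(f"{path}: missing VCF header before line {lineno}")
            parts = line.split("\t")
            if len(parts) < len(_VCF_COLUMNS):
                missing = _VCF_COLUMNS[len(parts) :]
                raise FormatError(
                    f"{path} line {lineno}: expected {len(_VCF_COLUMNS)} columns, "
                    f"got {len(parts)} (missing {', '.join(missing)})"
                )
            chrom, pos, _vid, ref, alt, _qual, _filt, info = parts[:8]
            kv = _parse_info(info)
            for key in ("DP", "AF"):
                if key not in kv:
                    raise FormatError(
                        f"{path} line {lineno}: INFO field {key} is required"
                    )
            try:
                vaf = float(kv["AF"])
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-numeric AF {kv['AF']!r}"
                ) from None
            try:
                depth = int(kv["DP"])
                pos_i = int(pos)
            except ValueError:
                raise FormatError(f"{path} line {lineno}: non-numeric POS/DP") from None
            interval = GenomicInterval(chrom, pos_i - 1, pos_i - 1 + len(ref))
            records.append(
                VariantRecord(
                    interval=interval,
                    ref_allele=ref,
                    alt_allele=alt,
                    vaf=vaf,
                    depth=depth,
                    consequence=kv.get("CONSEQUENCE", "noncoding"),
                    origin=kv.get("ORIGIN", "somatic"),
                )
            )
    if not saw_header:
        raise FormatError(f"{path}: not a VCF (no header lines)")
    return records


def _read_variant_tsv(path: str) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            vaf = float(row.vaf)
        except ValueError:
            raise FormatError(f"{path} line {i}: non-numeric vaf {row.vaf!r}") from None
        records.append(
            VariantRecord(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                ref_allele=row.ref,
                alt_allele=row.alt,
                vaf=vaf,
                depth=int(row.depth),
                consequence=row.consequence,
                origin=row.origin,
            )
        )
    return records


def write_variant_table(
    records: Sequence[VariantRecord], path: str, dialect: str = "vcf"
) -> None:
    """Write variants; ``read_variant_table`` round-trips the output."""
    if dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write(
                '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
            )
            fh.write(
                '##INFO=<ID=CONSEQUENCE,Number=1,Type=String,'
                'Description="Consequence class">\n'
            )
            fh.write(
                '##INFO=<ID=ORIGIN,Number=1,Type=String,'
                'Description="somatic or germline">\n'
            )
            fh.write("#" + "\t".join(_VCF_COLUMNS) + "\n")
            for r in records:
                info = (
                    f"DP={r.depth};AF={r.vaf!r};CONSEQUENCE={r.consequence};"
                    f"ORIGIN={r.origin}"
                )
                fh.write(
                    "\t".join(
                        [
                            r.interval.chrom,
                            str(r.interval.start + 1),
                            ".",
                            r.ref_allele,
                            r.alt_allele,
                            ".",
                            "PASS",
                            info,
                        ]
                    )
                    + "\n"
                )
    elif dialect == "tsv":
        rows = [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "ref": r.ref_allele,
                "alt": r.alt_allele,
                "vaf": repr(r.vaf),
                "depth": r.depth,
                "consequence": r.consequence,
                "origin": r.origin,
            }
            for r in records
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Microsatellite histograms
# ---------------------------------------------------------------------------

_MSI_COLUMNS = (
    "locus_id",
    "repeat_unit",
    "ref_repeats",
    "repeat_length",
    "tumor_reads",
    "normal_reads",
)


def read_msi_histograms(path: str) -> list[MicrosatelliteLocusProfile]:
    """Read per-locus repeat-length histograms from the long-format TSV.

    One row per (locus, repeat length) bin. An entirely empty
    ``normal_reads`` column marks a tumor-only run and yields profiles
    with ``normal_hist=None``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MSI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    tumor_only = df["normal_reads"].isna().all()
    profiles = []
    for locus_id, group in df.groupby("locus_id", sort=False):
        dup = group["repeat_length"].duplicated()
        if dup.any():
            raise FormatError(
                f"{path}: duplicate repeat_length bin at locus {locus_id}"
            )
        if (group["tumor_reads"] < 0).any() or (
            not tumor_only and (group["normal_reads"] < 0).any()
        ):
            raise FormatError(f"{path}: negative read count at locus {locus_id}")
        tumor_hist = dict(
            zip(group["repeat_length"].astype(int), group["tumor_reads"].astype(int))
        )
        normal_hist = (
            None
            if tumor_only
            else dict(
                zip(
                    group["repeat_length"].astype(int),
                    group["normal_reads"].astype(int),
                )
            )
        )
        flank_ok = (
            bool(group["flank_ok"].all()) if "flank_ok" in group.columns else True
        )
        profiles.append(
            MicrosatelliteLocusProfile(
                locus_id=str(locus_id),
                repeat_unit=str(group["repeat_unit"].iloc[0]),
                ref_repeats=int(group["ref_repeats"].iloc[0]),
                tumor_hist=tumor_hist,
                normal_hist=normal_hist,
                flank_ok=flank_ok,
            )
        )
    return profiles


def write_msi_histograms(
    profiles: Sequence[MicrosatelliteLocusProfile], path: str
) -> None:
    rows = []
    for p in profiles:
        lengths = sorted(
            set(p.tumor_hist) | set(p.normal_hist if p.normal_hist else ())
        )
        for length in lengths:
            rows.append(
                {
                    "locus_id": p.locus_id,
                    "repeat_unit": p.repeat_unit,
                    "ref_repeats": p.ref_repeats,
                    "repeat_length": length,
                    "tumor_reads": p.tumor_hist.get(length, 0),
                    "normal_reads": ""
                    if p.normal_hist is None
                    else p.normal_hist.get(length, 0),
                    "flank_ok": p.flank_ok,
                }
            )
    pd.DataFrame(rows, columns=_MSI_COLUMNS + ("flank_ok",)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Coverage / het-SNV / BED / BEDPE tables
# ---------------------------------------------------------------------------


def read_coverage_table(path: str) -> list[TargetCoverage]:
    """TSV: chrom, start, end, gene, tumor_depth, normal_depth[, gc]."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "gene", "tumor_depth", "normal_depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        gc = getattr(row, "gc", None)
        out.append(
            TargetCoverage(
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                gene=str(row.gene),
                tumor_depth=float(row.tumor_depth),
                normal_depth=float(row.normal_depth),
                gc_fraction=None if gc is None or pd.isna(gc) else float(gc),
            )
        )
    return out


def write_coverage_table(targets: Sequence[TargetCoverage], path: str) -> None:
    rows = [
        {
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "gene": t.gene,
            "tumor_depth": repr(t.tumor_depth),
            "normal_depth": repr(t.normal_depth),
            "gc": "" if t.gc_fraction is None else repr(t.gc_fraction),
        }
        for t in targets
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene", "tumor_depth", "normal_depth", "gc"],
    ).to_csv(path, sep="\t", index=False)


def read_hetsnv_table(path: str) -> list[HetSnvObservation]:
    """TSV: chrom, pos (0-based), tumor_alt_fraction, tumor_depth."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "tumor_alt_fraction", "tumor_depth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        HetSnvObservation(
            interval=GenomicInterval(str(r.chrom), int(r.pos), int(r.pos) + 1),
            tumor_alt_fraction=float(r.tumor_alt_fraction),
            tumor_depth=int(r.tumor_depth),
        )
        for r in df.itertuples(index=False)
    ]


def write_hetsnv_table(snvs: Sequence[HetSnvObservation], path: str) -> None:
    rows = [
        {
            "chrom": s.interval.chrom,
            "pos": s.interval.start,
            "tumor_alt_fraction": repr(s.tumor_alt_fraction),
            "tumor_depth": s.tumor_depth,
        }
        for s in snvs
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "tumor_alt_fraction", "tumor_depth"]
    ).to_csv(path, sep="\t", index=False)


def read_bed_intervals(path: str) -> list[tuple[str, GenomicInterval]]:
    """Read BED3+1 as (name, interval) pairs; name defaults to the row index."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else str(lineno)
            out.append(
                (name, GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            )
    return out


def write_bed_intervals(
    regions: Iterable[tuple[str, GenomicInterval]], path: str
) -> None:
    with open(path, "w") as fh:
        for name, iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_sv_bedpe(path: str) -> list[SvCandidate]:
    """Read the 10-column BEDPE dialect used for SV candidates.

    Columns: chrom_a, start_a, end_a, chrom_b, start_b, end_b, name,
    sv_class, strand_a, strand_b, split_reads, discordant_reads.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"{path} line {lineno}: expected 12 BEDPE columns, got {len(parts)}"
                )
            (ca, sa, ea, cb, sb, eb, name, svc, stra, strb, split, disc) = parts[:12]
            out.append(
                SvCandidate(
                    end_a=GenomicInterval(ca, int(sa), int(ea), stra),
                    end_b=GenomicInterval(cb, int(sb), int(eb), strb),
                    name=name,
                    sv_class=svc,
                    split_reads=int(split),
                    discordant_reads=int(disc),
                )
            )
    return out


def write_sv_bedpe(candidates: Sequence[SvCandidate], path: str) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            c.end_a.chrom,
                            c.end_a.start,
                            c.end_a.end,
                            c.end_b.chrom,
                            c.end_b.start,
                            c.end_b.end,
                            c.name,
                            c.sv_class,
                            c.end_a.strand,
                            c.end_b.strand,
                            c.split_reads,
                            c.discordant_reads,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Transcript / domain models (JSON)
# ---------------------------------------------------------------------------


def read_transcript_models(
    path: str,
) -> tuple[list[TranscriptModel], list[DomainAnnotation]]:
    """Load transcript and protein-domain models from the JSON schema.

    Top-level keys: ``transcripts`` (list) and optional ``domains``
    (list). Exon coordinates are 0-based half-open; validation errors
    name the offending transcript.
    """
    with open(path) as fh:
        doc = json.load(fh)
    transcripts = []
    for t in doc.get("transcripts", []):
        tid = t.get("transcript_id", "<unnamed>")
        try:
            exons = tuple(
                GenomicInterval(t["chrom"], int(s), int(e)) for s, e in t["exons"]
            )
            promoter = None
            if t.get("promoter") is not None:
                ps, pe = t["promoter"]
                promoter = GenomicInterval(t["chrom"], int(ps), int(pe))
            transcripts.append(
                TranscriptModel(
                    gene_id=t["gene_id"],
                    transcript_id=tid,
                    strand=t["strand"],
                    exons=exons,
                    cds_start=int(t["cds_start"]),
                    cds_end=int(t["cds_end"]),
                    promoter=promoter,
                    protein_id=t.get("protein_id"),
                    exon_sequences=tuple(t["exon_sequences"])
                    if t.get("exon_sequences")
                    else None,
                )
            )
        except ParameterError as exc:
            raise FormatError(f"{path}: transcript {tid}: {exc}") from exc
        except KeyError as exc:
            raise FormatError(f"{path}: transcript {tid}: missing key {exc}") from exc
    domains = [
        DomainAnnotation(
            protein_id=d["protein_id"],
            name=d["name"],
            aa_start=int(d["aa_start"]),
            aa_end=int(d["aa_end"]),
        )
        for d in doc.get("domains", [])
    ]
    return transcripts, domains


def write_transcript_models(
    transcripts: Sequence[TranscriptModel],
    domains: Sequence[DomainAnnotation],
    path: str,
) -> None:
    doc = {
        "transcripts": [
            {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "exons": [[e.start, e.end] for e in t.exons],
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
                "promoter": None
                if t.promoter is None
                else [t.promoter.start, t.promoter.end],
                "protein_id": t.protein_id,
                "exon_sequences": list(t.exon_sequences)
                if t.exon_sequences
                else None,
            }
            for t in transcripts
        ],
        "domains": [
            {
                "protein_id": d.protein_id,
                "name": d.name,
                "aa_start": d.aa_start,
                "aa_end": d.aa_end,
            }
            for d in domains
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
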