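"""Synthetic input generators with the statistical structure each stage assumes.

Every generator is a pure function of an explicit seed (NumPy
``default_rng``; no global state) and emits truth labels alongside the
simulated data so downstream tests are self-checking. The generators
emulate the statistical behavior of clinical specimens and reference
standards — stutter noise around microsatellite repeat lengths, binomial
VAF sampling at finite depth, stromal admixture of copy-number signal,
lognormal coverage noise — not read-level sequencing artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from oncopanel.core_io import (
    CONSEQUENCES,
    GenomicInterval,
    HetSnvObservation,
    MicrosatelliteLocusProfile,
    SvCandidate,
    TargetCoverage,
    TranscriptModel,
    VariantRecord,
)
from oncopanel.errors import ParameterError

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# default consequence mix for simulated somatic variant sets
_CONSEQUENCE_PROBS = {
    "missense": 0.50,
    "synonymous": 0.18,
    "nonsense": 0.05,
    "stop_loss": 0.02,
    "frameshift_indel": 0.10,
    "inframe_indel": 0.05,
    "noncoding": 0.10,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated MSI specimen.

    ``instability_shift`` is the mean repeat-count contraction at
    affected loci of an MSI-H tumor (microsatellites predominantly
    shorten under mismatch-repair deficiency); ``stutter_rate`` is the
    per-step probability of the symmetric geometric PCR-stutter process
    around the true repeat count.
    """

    seed: int
    n_loci: int = 43
    purity: float = 1.0
    depth_mean: float = 200.0
    status: str = "MSS"
    stutter_rate: float = 0.10
    instability_shift: float = 3.0
    affected_locus_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in ("purity", "stutter_rate", "affected_locus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be positive")
        if self.status not in ("MSI-H", "MSS"):
            raise ParameterError(f"status must be MSI-H or MSS, got {self.status!r}")
        if self.instability_shift <= 0:
            raise ParameterError("instability_shift must be positive")


@dataclass(frozen=True)
class MsiSimulation:
    """Simulated MSI specimen: locus profiles plus truth labels."""

    profiles: tuple[MicrosatelliteLocusProfile, ...]
    affected_loci: frozenset[str]
    spec: SimulationSpec


def _panel_layout(n_loci: int) -> list[tuple[str, str, int]]:
    """Fixed (locus_id, repeat_unit, ref_repeats) layout of the toy panel.

    The layout is a panel property, deliberately independent of the
    simulation seed, so feature vectors from different simulated samples
    align locus-by-locus.
    """
    units = ("A", "T", "C", "AT", "CA")
    return [
        (f"MS{i + 1:02d}", units[i % len(units)], 10 + (i % 11))
        for i in range(n_loci)
    ]


def _stutter_lengths(
    rng: np.random.Generator, center: float, rate: float, n: int
) -> np.ndarray:
    """Repeat lengths = round(center) +/- geometric stutter magnitude."""
    if n == 0:
        return np.zeros(0, dtype=int)
    mags = rng.geometric(1.0 - rate, size=n) - 1
    signs = rng.choice([-1, 1], size=n)
    lengths = np.rint(center).astype(int) + mags * signs
    return np.maximum(lengths, 1)


def simulate_msi_profiles(spec: SimulationSpec) -> MsiSimulation:
    """Simulate paired tumor/normal repeat-length histograms for one specimen.

    The normal sample draws read lengths from the reference repeat count
    with symmetric geometric stutter. An MSS tumor draws from the same
    process. An MSI-H tumor draws, at each affected locus, a
    ``purity``-weighted mixture of an unstable process (mean shifted down
    by ``instability_shift`` repeats with doubled stutter rate — variance
    inflation) and the normal process, emulating stromal admixture in a
    dilution series.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _panel_layout(spec.n_loci)
    n_affected = int(round(spec.affected_locus_fraction * spec.n_loci))
    affected_idx = (
        set(rng.choice(spec.n_loci, size=n_affected, replace=False))
        if spec.status == "MSI-H"
        else set()
    )
    unstable_rate = min(0.45, 2.0 * spec.stutter_rate)

    profiles = []
    affected_ids = set()
    for i, (locus_id, unit, ref_repeats) in enumerate(layout):
        n_normal = int(rng.poisson(spec.depth_mean))
        n_tumor = int(rng.poisson(spec.depth_mean))
        normal_lengths = _stutter_lengths(rng, ref_repeats, spec.stutter_rate, n_normal)
        if i in affected_idx:
            affected_ids.add(locus_id)
            from_tumor = rng.random(n_tumor) < spec.purity
            n_unstable = int(from_tumor.sum())
            unstable = _stutter_lengths(
                rng, ref_repeats - spec.instability_shift, unstable_rate, n_unstable
            )
            stable = _stutter_lengths(
                rng, ref_repeats, spec.stutter_rate, n_tumor - n_unstable
            )
            tumor_lengths = np.concatenate([unstable, stable])
        else:
            tumor_lengths = _stutter_lengths(
                rng, ref_repeats, spec.stutter_rate, n_tumor
            )
        tumor_vals, tumor_counts = np.unique(tumor_lengths, return_counts=True)
        normal_vals, normal_counts = np.unique(normal_lengths, return_counts=True)
        profiles.append(
            MicrosatelliteLocusProfile(
                locus_id=locus_id,
                repeat_unit=unit,
                ref_repeats=ref_repeats,
                tumor_hist=dict(zip(tumor_vals.tolist(), tumor_counts.tolist())),
                normal_hist=dict(zip(normal_vals.tolist(), normal_counts.tolist())),
            )
        )
    return MsiSimulation(
        profiles=tuple(profiles), affected_loci=frozenset(affected_ids), spec=spec
    )


@dataclass(frozen=True)
class SimulatedVariants:
    """Simulated variant records plus the latent true VAF of each."""

    records: tuple[VariantRecord, ...]
    true_vafs: tuple[float, ...]
    depth_mean: float
    seed: int


def simulate_variant_set(
    n: int,
    vaf_values: list[float],
    depth_mean: float,
    seed: int,
    consequence_probs: dict[str, float] | None = None,
) -> SimulatedVariants:
    """Simulate ``n`` somatic variants with binomial VAF sampling.

    Each variant's observed VAF is Binomial(depth, true VAF) / depth with
    depth drawn Poisson around ``depth_mean``; true VAFs cycle through
    ``vaf_values``. Consequence classes are drawn from a categorical
    distribution (default :data:`_CONSEQUENCE_PROBS`).
    """
    if n < 0:
        raise ParameterError("n must be non-negative")
    for v in vaf_values:
        if not 0.0 < v <= 1.0:
            raise ParameterError(f"true VAF {v} outside (0, 1]")
    probs = consequence_probs or _CONSEQUENCE_PROBS
    if set(probs) - set(CONSEQUENCES):
        raise ParameterError("unknown consequence class in probabilities")
    names = list(probs)
    weights = np.asarray([probs[c] for c in names], dtype=float)
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    records, true_vafs = [], []
    for i in range(n):
        true_vaf = float(vaf_values[i % len(vaf_values)]) if vaf_values else 0.5
        depth = max(1, int(rng.poisson(depth_mean)))
        observed = int(rng.binomial(depth, true_vaf)) / depth
        consequence = names[int(rng.choice(len(names), p=weights))]
        if consequence in ("frameshift_indel", "inframe_indel"):
            ref, alt = ("ATT", "A") if consequence == "inframe_indel" else ("AT", "A")
        else:
            ref, alt = "A", "G"
        start = 1000 + 100 * i
        records.append(
            VariantRecord(
                interval=GenomicInterval("1", start, start + len(ref)),
                ref_allele=ref,
                alt_allele=alt,
                vaf=observed,
                depth=depth,
                consequence=consequence,
                origin="somatic",
            )
        )
        true_vafs.append(true_vaf)
    return SimulatedVariants(
        records=tuple(records),
        true_vafs=tuple(true_vafs),
        depth_mean=depth_mean,
        seed=seed,
    )


def dilute_variants(sim: SimulatedVariants, n_halvings: int) -> SimulatedVariants:
    """Apply ``n_halvings`` serial 1:1 dilutions with matched normal.

    Each true VAF is multiplied by 2^(-n_halvings) and the observed VAF
    re-sampled binomially at a freshly drawn depth (seed derived from the
    parent simulation's seed and the dilution step, so a dilution series
    is reproducible end-to-end).
    """
    if n_halvings < 0:
        raise ParameterError("n_halvings must be non-negative")
    factor = 2.0 ** (-n_halvings)
    rng = np.random.default_rng((sim.seed, n_halvings))
    records, true_vafs = [], []
    for rec, true_vaf in zip(sim.records, sim.true_vafs):
        new_true = true_vaf * factor
        depth = max(1, int(rng.poisson(sim.depth_mean)))
        observed = int(rng.binomial(depth, new_true)) / depth
        records.append(
            VariantRecord(
                interval=rec.interval,
                ref_allele=rec.ref_allele,
                alt_allele=rec.alt_allele,
                vaf=observed,
                depth=depth,
                consequence=rec.consequence,
                origin=rec.origin,
            )
        )
        true_vafs.append(new_true)
    return SimulatedVariants(
        records=tuple(records),
        true_vafs=tuple(true_vafs),
        depth_mean=sim.depth_mean,
        seed=sim.seed,
    )


@dataclass(frozen=True)
class CoverageSimulation:
    """Simulated coverage profile plus the truth copy number per gene."""

    targets: tuple[TargetCoverage, ...]
    het_snvs: tuple[HetSnvObservation, ...]
    truth_cn: dict[str, int] = field(default_factory=dict)
    purity: float = 1.0


def simulate_coverage_profile(
    targets: list[GenomicInterval],
    events: list[tuple[str, int]],
    purity: float,
    noise_sd: float,
    seed: int,
    depth_mean: float = 500.0,
    genes: list[str] | None = None,
    het_snv_rate: float = 0.25,
) -> CoverageSimulation:
    """Simulate tumor/normal target depths and het-SNV allele fractions.

    Tumor depth at a target with integer copy number ``c`` has mean
    proportional to ``purity * c/2 + (1 - purity)`` (the stromal
    admixture mixture), with lognormal multiplicative noise of log-scale
    standard deviation ``noise_sd``. Het-SNV alternate fractions are
    binomial around the mixture expectation assuming the amplified
    haplotype carries either 1 or ``c - 1`` alternate copies (chosen at
    random per SNV).
    """
    if not targets:
        raise ParameterError("empty target list")
    if not 0.0 <= purity <= 1.0:
        raise ParameterError(f"purity {purity} outside [0, 1]")
    cn_by_gene = {}
    for gene, cn in events:
        if cn < 0 or int(cn) != cn:
            raise ParameterError(f"copy number for {gene} must be a non-negative int")
        cn_by_gene[gene] = int(cn)
    if genes is None:
        genes = [f"GENE{i // 4}" for i in range(len(targets))]
    rng = np.random.default_rng(seed)
    out_targets, het_snvs, truth = [], [], {}
    for iv, gene in zip(targets, genes):
        cn = cn_by_gene.get(gene, 2)
        truth[gene] = cn
        mix = purity * cn / 2.0 + (1.0 - purity)
        normal = depth_mean * float(rng.lognormal(0.0, noise_sd)) if noise_sd > 0 else depth_mean
        tumor = (
            depth_mean * mix * float(rng.lognormal(0.0, noise_sd))
            if noise_sd > 0
            else depth_mean * mix
        )
        out_targets.append(
            TargetCoverage(
                interval=iv, gene=gene, tumor_depth=tumor, normal_depth=normal
            )
        )
        if rng.random() < het_snv_rate:
            total = purity * cn + 2.0 * (1.0 - purity)
            alt_copies = 1 if (cn < 2 or rng.random() < 0.5) else cn - 1
            expect = (
                (purity * alt_copies + (1.0 - purity)) / total if total > 0 else 0.5
            )
            depth = max(1, int(rng.poisson(depth_mean * max(mix, 1e-6))))
            alt = int(rng.binomial(depth, min(max(expect, 0.0), 1.0)))
            pos = (iv.start + iv.end) // 2
            het_snvs.append(
                HetSnvObservation(
                    interval=GenomicInterval(iv.chrom, pos, pos + 1),
                    tumor_alt_fraction=alt / depth,
                    tumor_depth=depth,
                )
            )
    return CoverageSimulation(
        targets=tuple(out_targets),
        het_snvs=tuple(het_snvs),
        truth_cn=truth,
        purity=purity,
    )


@dataclass(frozen=True)
class FusionTruth:
    """Expected breakpoint placement for one simulated fusion partner."""

    gene_id: str
    role: str
    anchor_exon: int | None
    retained_exons: frozenset[int]
    promoter_only: bool


@dataclass(frozen=True)
class FusionSimulation:
    candidate: SvCandidate
    truth_5p: FusionTruth
    truth_3p: FusionTruth


def _exons_upstream(t: TranscriptModel, position: int, reverse: bool) -> list[int]:
    """1-based genomic exon indices strictly upstream of ``position``.

    Upstream is in the transcript's direction of transcription, reversed
    when ``reverse`` (an inverted gene in the rearrangement).
    """
    forward = (t.strand == "+") != reverse
    if forward:
        return [i + 1 for i, e in enumerate(t.exons) if e.end <= position]
    return [i + 1 for i, e in enumerate(t.exons) if e.start >= position]


def simulate_fusion_case(
    t5: TranscriptModel,
    t3: TranscriptModel,
    breakpoint5: int,
    breakpoint3: int,
    inversion: bool = False,
    split_reads: int = 10,
    discordant_reads: int = 10,
) -> FusionSimulation:
    """Construct a BEDPE fusion candidate with self-checking truth labels.

    Truth labels are derived from direct interval arithmetic on the exon
    table (which exons lie transcriptionally upstream/downstream of each
    breakpoint), independent of the annotation walk used by the fusion
    stage, so placement tests are not circular.
    """
    for t, bp in ((t5, breakpoint5), (t3, breakpoint3)):
        lo = min(t.exons[0].start, t.promoter.start if t.promoter else t.exons[0].start)
        hi = max(t.exons[-1].end, t.promoter.end if t.promoter else t.exons[-1].end)
        span = hi - lo
        if bp < lo - 10 * span or bp > hi + 10 * span:
            raise ParameterError(
                f"breakpoint {bp} far beyond transcript {t.transcript_id}"
            )
    up5 = _exons_upstream(t5, breakpoint5, reverse=False)
    order5 = [i + 1 for i in t5.exon_order()]  # 1-based, transcription order
    truth5 = FusionTruth(
        gene_id=t5.gene_id,
        role="five_prime",
        anchor_exon=max(up5, key=order5.index) if up5 else None,
        retained_exons=frozenset(up5),
        promoter_only=not up5,
    )
    up3 = set(_exons_upstream(t3, breakpoint3, reverse=inversion))
    down3 = [i + 1 for i in range(len(t3.exons)) if (i + 1) not in up3]
    order3 = [i + 1 for i in t3.exon_order()]
    if inversion:
        order3 = order3[::-1]  # effective transcription order of the inverted gene
    truth3 = FusionTruth(
        gene_id=t3.gene_id,
        role="three_prime",
        anchor_exon=min(down3, key=order3.index) if down3 else None,
        retained_exons=frozenset(down3),
        promoter_only=False,
    )
    if t5.chrom != t3.chrom:
        sv_class = "translocation"
    elif inversion:
        sv_class = "inversion"
    else:
        sv_class = "deletion"
    candidate = SvCandidate(
        end_a=GenomicInterval(t5.chrom, max(breakpoint5 - 1, 0), breakpoint5 + 1, "+"),
        end_b=GenomicInterval(
            t3.chrom,
            max(breakpoint3 - 1, 0),
            breakpoint3 + 1,
            "-" if inversion else "+",
        ),
        name=f"{t5.gene_id}-{t3.gene_id}",
        sv_class=sv_class,
        split_reads=split_reads,
        discordant_reads=discordant_reads,
    )
    return FusionSimulation(candidate=candidate, truth_5p=truth5, truth_3p=truth3)


def toy_transcript(
    gene_id: str,
    chrom: str = "1",
    strand: str = "+",
    n_exons: int = 4,
    exon_length: int = 90,
    intron_length: int = 110,
    offset: int = 1000,
    seed: int = 0,
    promoter_length: int = 200,
) -> TranscriptModel:
    """A toy protein-coding transcript with deterministic exon sequences.

    The CDS spans all exons (ATG at the transcriptional start, in frame);
    exon length is a multiple of 3 by default so toy fusion frames are
    easy to reason about.
    """
    if exon_length % 3:
        raise ParameterError("toy exon_length must be a codon multiple")
    rng = np.random.default_rng(
        (seed, int.from_bytes(hashlib.sha256(gene_id.encode()).digest()[:4], "big"))
    )
    # stop-free mRNA so toy fusion products only stop at the native terminus
    sense_codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    n_codons = n_exons * exon_length // 3
    mrna = "ATG" + "".join(
        rng.choice(sense_codons, size=n_codons - 1)
    )
    exons = []
    pos = offset
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_length))
        pos += exon_length + intron_length
    mrna_slices = [
        mrna[i * exon_length : (i + 1) * exon_length] for i in range(n_exons)
    ]
    if strand == "+":
        seqs = mrna_slices
        promoter = GenomicInterval(
            chrom, max(offset - promoter_length, 0), offset
        )
    else:
        from Bio.Seq import Seq

        # genomic order is the reverse of transcription order on minus strand
        seqs = [
            str(Seq(s).reverse_complement()) for s in reversed(mrna_slices)
        ]
        promoter = GenomicInterval(
            chrom, exons[-1].end, exons[-1].end + promoter_length
        )
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}-201",
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0].start,
        cds_end=exons[-1].end,
        promoter=promoter,
        protein_id=f"{gene_id}-P1",
        exon_sequences=tuple(seqs),
    )


def toy_affinity_predictor(peptide: str, allele: str) -> float:
    """Deterministic, seed-free stand-in for a trained MHC-I affinity model.

    Maps a SHA-256 hash of the (peptide, allele) pair to [1, 50000] nM.
    This is a synthetic predictor for testing the antigenicity logic; it
    carries no biochemical information. Identical inputs always give
    identical outputs across runs and platforms.
    """
    if not 8 <= len(peptide) <= 11:
        raise ParameterError(f"peptide length {len(peptide)} outside 8-11")
    bad = set(peptide) - _AA_ALPHABET
    if bad:
        raise ParameterError(f"invalid amino-acid letter(s) {sorted(bad)}")
    digest = hashlib.sha256(f"{peptide}|{allele}".encode()).digest()
    value = int.from_bytes(digest[:8], "big")
    return 1.0 + (value % 4_999_900) / 100.0  # [1, 50000] nM in 0.01 steps
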