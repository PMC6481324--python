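"""Gene-rearrangement filtering, breakpoint placement, and chimeric products.

Structural-variant candidates are filtered to the assay's reportable
regions and a minimum read-support rule; surviving breakpoints are
snapped, walking in the direction of transcription (reversed for the
inverted gene of an inversion), to the boundary adjacent to the next
exon. The 5' partner donates its transcriptionally upstream exons (or
only its promoter, TMPRSS2-ERG style), the 3' partner its downstream
exons; the chimeric CDS is the concatenation of the two coding
contributions, translated to the first stop, with functional domains
reported as retained when they lie entirely inside a partner's
contributed region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from oncopanel.core_io import (
    AssayConfig,
    DomainAnnotation,
    GenomicInterval,
    SvCandidate,
    TranscriptModel,
)
from oncopanel.errors import ParameterError, PlacementError, ProductError

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class BreakpointPlacement:
    """An exon-anchored breakpoint on one fusion partner.

    ``anchor_exon`` and ``retained_exons`` are 1-based genomic exon
    indices; ``side`` says on which genomic side of the anchor exon the
    junction lies. A five-prime placement upstream of every exon retains
    only the promoter.
    """

    transcript: TranscriptModel
    role: str
    retained_exons: frozenset[int]
    anchor_exon: int | None
    side: str | None  # before_exon | after_exon
    promoter_retained: bool = False
    inverted: bool = False


@dataclass(frozen=True)
class ChimericProduct:
    """The fused coding sequence and its translation.

    ``junction_aa_position`` counts the complete codons contributed by
    the 5' partner; ``three_prime_first_aa`` is the first fully retained
    residue of the 3' partner's native protein (1-based), used for
    domain-retention bookkeeping.
    """

    fused_cds: str
    fused_protein: str
    frame_status: str  # in_frame | out_of_frame | promoter_swap
    junction_aa_position: int
    three_prime_first_aa: int | None


# ---------------------------------------------------------------------------
# Candidate filters
# ---------------------------------------------------------------------------


def in_dna_reportable_range(
    candidate: SvCandidate, regions: list[tuple[str, GenomicInterval]]
) -> bool:
    """True when at least one breakpoint end overlaps a reportable region."""
    return any(
        end.overlaps(region)
        for end in (candidate.end_a, candidate.end_b)
        for _, region in regions
    )


def evidence_filter(candidate: SvCandidate, config: AssayConfig | None = None) -> bool:
    """Read-support reporting rule: total support >= threshold, >= 1 split."""
    config = config or AssayConfig()
    total = candidate.split_reads + candidate.discordant_reads
    return total >= config.fusion_min_support and candidate.split_reads >= 1


# ---------------------------------------------------------------------------
# Breakpoint placement
# ---------------------------------------------------------------------------


def place_breakpoint(
    transcript: TranscriptModel,
    position: int,
    role: str,
    inverted: bool = False,
) -> BreakpointPlacement:
    """Snap a genomic breakpoint to the exon boundary the fusion rule implies.

    Walking in the direction of transcription — reversed when the gene is
    the inverted partner of an inversion — the junction is placed at the
    boundary adjacent to the next exon. Exons wholly upstream of the
    junction (in the walking direction) are the 5'-role retention set;
    exons wholly downstream are the 3'-role set, so a breakpoint exactly
    on an exon boundary resolves to the intron side. A five-prime
    breakpoint upstream of all exons retains only the promoter.
    """
    if role not in (FIVE_PRIME, THREE_PRIME):
        raise ParameterError(f"unknown role {role!r}")
    forward = (transcript.strand == "+") != inverted
    exons = transcript.exons
    if forward:
        upstream = [i + 1 for i, e in enumerate(exons) if e.end <= position]
        downstream = [i + 1 for i, e in enumerate(exons) if e.start >= position]
    else:
        upstream = [i + 1 for i, e in enumerate(exons) if e.start >= position]
        downstream = [i + 1 for i, e in enumerate(exons) if e.end <= position]
    order = [i + 1 for i in transcript.exon_order()]
    if inverted:
        order = order[::-1]

    if role == FIVE_PRIME:
        retained = upstream
        if not retained:
            return BreakpointPlacement(
                transcript=transcript,
                role=role,
                retained_exons=frozenset(),
                anchor_exon=None,
                side=None,
                promoter_retained=True,
                inverted=inverted,
            )
        anchor = max(retained, key=order.index)
        side = "after_exon" if forward else "before_exon"
    else:
        retained = downstream
        if not retained:
            raise PlacementError(
                f"{transcript.transcript_id}: breakpoint {position} leaves no "
                f"exon on the retained (3') side"
            )
        anchor = min(retained, key=order.index)
        side = "before_exon" if forward else "after_exon"
    return BreakpointPlacement(
        transcript=transcript,
        role=role,
        retained_exons=frozenset(retained),
        anchor_exon=anchor,
        side=side,
        promoter_retained=False,
        inverted=inverted,
    )


# ---------------------------------------------------------------------------
# Chimeric product construction
# ---------------------------------------------------------------------------


def _exon_mrna_sequence(t: TranscriptModel, genomic_index: int) -> str:
    """mRNA-oriented sequence of one exon (0-based genomic index)."""
    if t.exon_sequences is None:
        raise ProductError(f"{t.transcript_id}: no exon sequences in the model")
    seq = t.exon_sequences[genomic_index]
    return seq if t.strand == "+" else str(Seq(seq).reverse_complement())


def _coding_slice(t: TranscriptModel, genomic_index: int) -> str:
    """mRNA-oriented coding portion of one exon (may be empty)."""
    exon = t.exons[genomic_index]
    lo = max(exon.start, t.cds_start)
    hi = min(exon.end, t.cds_end)
    if lo >= hi:
        return ""
    mrna = _exon_mrna_sequence(t, genomic_index)
    if t.strand == "+":
        return mrna[lo - exon.start : hi - exon.start]
    return mrna[exon.end - hi : exon.end - lo]


def _coding_contribution(placement: BreakpointPlacement) -> str:
    """Concatenated coding sequence of the retained exons, reading order."""
    t = placement.transcript
    pieces = [
        _coding_slice(t, i)
        for i in t.exon_order()
        if (i + 1) in placement.retained_exons
    ]
    return "".join(pieces)


def _native_cds(t: TranscriptModel) -> str:
    return "".join(_coding_slice(t, i) for i in t.exon_order())


def _translate(cds: str) -> str:
    usable = cds[: 3 * (len(cds) // 3)]
    if not usable:
        return ""
    return str(Seq(usable).translate(to_stop=True))


def build_chimeric_product(
    p5: BreakpointPlacement, p3: BreakpointPlacement
) -> ChimericProduct:
    """Join the 5' and 3' coding contributions and translate the result.

    The product is in frame when the 5' coding length is congruent mod 3
    with the CDS offset at which the 3' contribution begins, i.e. the 3'
    partner is read in its native frame. A promoter-only 5' contribution
    yields the 3' partner's intact native ORF under the new promoter
    (``promoter_swap``). Translation stops at the first stop codon.
    """
    if p5.role != FIVE_PRIME or p3.role != THREE_PRIME:
        raise ParameterError("need a five_prime and a three_prime placement")
    t3 = p3.transcript
    if p5.promoter_retained and not p5.retained_exons:
        cds3 = _native_cds(t3)
        protein = _translate(cds3)
        return ChimericProduct(
            fused_cds=cds3,
            fused_protein=protein,
            frame_status="promoter_swap",
            junction_aa_position=0,
            three_prime_first_aa=1,
        )
    cds5 = _coding_contribution(p5)
    cds3 = _coding_contribution(p3)
    if not cds5 and not cds3:
        raise ProductError("no coding sequence on either side of the junction")
    # CDS offset of the 3' contribution within its native transcript
    offset3 = sum(
        len(_coding_slice(t3, i))
        for i in t3.exon_order()
        if (i + 1) not in p3.retained_exons
    )
    in_frame = cds3 != "" and (len(cds5) % 3) == (offset3 % 3)
    fused = cds5 + cds3
    frame_status = "in_frame" if in_frame else "out_of_frame"
    first_aa = None
    if cds3:
        # first complete native codon inside the retained 3' suffix
        first_aa = offset3 // 3 + 1 if offset3 % 3 == 0 else offset3 // 3 + 2
    return ChimericProduct(
        fused_cds=fused,
        fused_protein=_translate(fused),
        frame_status=frame_status,
        junction_aa_position=len(cds5) // 3,
        three_prime_first_aa=first_aa,
    )


def retained_domains(
    product: ChimericProduct,
    domains_5: list[DomainAnnotation],
    domains_3: list[DomainAnnotation],
) -> tuple[list[DomainAnnotation], list[DomainAnnotation]]:
    """Domains wholly inside each partner's contributed region.

    A 5' domain is retained when it ends at or before the junction codon;
    a 3' domain when it starts at or after the first retained native
    residue and the 3' partner is read in its native frame (in-frame or
    promoter-swap products). Domains straddling the junction are not
    reported: a partial domain's function is ambiguous.
    """
    if product.frame_status == "promoter_swap":
        return [], list(domains_3)
    kept5 = [d for d in domains_5 if d.aa_end <= product.junction_aa_position]
    kept3: list[DomainAnnotation] = []
    if product.frame_status == "in_frame" and product.three_prime_first_aa is not None:
        kept3 = [d for d in domains_3 if d.aa_start >= product.three_prime_first_aa]
    return kept5, kept3


# ---------------------------------------------------------------------------
# RNA count normalization
# ---------------------------------------------------------------------------


def normalize_rna_counts(
    counts: pd.DataFrame,
    gc: pd.Series,
    length: pd.Series,
    n_bins: int = 10,
) -> pd.DataFrame:
    """GC/length full-quantile normalization plus median-of-ratios size factors.

    Genes are binned by GC and length deciles. Within each sample, a
    full-quantile step maps every bin's value distribution onto the mean
    quantile curve across bins, removing monotone GC/length trends; a
    single bin makes the step an identity. Sequencing depth is then
    removed by DESeq-style size factors (per-sample median of ratios to
    the gene-wise geometric mean).
    """
    if (counts.values < 0).any():
        raise ParameterError("negative counts")
    gc = gc.reindex(counts.index)
    length = length.reindex(counts.index)
    if gc.isna().any() or length.isna().any():
        raise ParameterError("gc/length missing for some genes")
    if (length <= 0).any():
        raise ParameterError("gene with zero or negative length")

    def _deciles(values: pd.Series) -> pd.Series:
        if values.nunique() < 2:
            return pd.Series(0, index=values.index)
        return pd.qcut(values.rank(method="first"), q=n_bins, labels=False)

    bins = _deciles(gc).astype(str) + "|" + _deciles(length).astype(str)
    out = counts.astype(float).copy()
    groups = {b: idx for b, idx in counts.groupby(bins).groups.items()}

    for sample in counts.columns:
        col = counts[sample].astype(float)
        # quantile grid points of each bin's empirical quantile function
        curves = {}
        for b, idx in groups.items():
            v = np.sort(col.loc[idx].values)
            q = (np.arange(len(v)) + 0.5) / len(v)
            curves[b] = (q, v)
        for b, idx in groups.items():
            v = col.loc[idx].values
            m = len(v)
            ranks = np.argsort(np.argsort(v, kind="stable"), kind="stable")
            qv = (ranks + 0.5) / m
            target = np.mean(
                [np.interp(qv, cq, cv) for cq, cv in curves.values()], axis=0
            )
            out.loc[idx, sample] = target
    # size factors on the quantile-normalized matrix
    vals = out.values
    with np.errstate(divide="ignore"):
        logs = np.log(vals)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ParameterError("no gene expressed in all samples; size factors undefined")
    log_geomean = logs[finite].mean(axis=1)
    size_factors = np.exp(
        np.median(logs[finite] - log_geomean[:, None], axis=0)
    )
    return out / size_factors
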