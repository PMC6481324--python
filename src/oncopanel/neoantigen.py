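"""Neoantigen determination from mutant peptides and class-I HLA genotypes.

All 8-11-mer peptides overlapping at least one mutated residue are
enumerated from the mutant protein; each peptide is scored against each
of the patient's HLA class I alleles with a pluggable affinity predictor
(alleles the predictor does not support fall back to the nearest
supported allele by amino-acid homology of the binding domain); the
mutation is antigenic when any peptide binds any allele below 500 nM.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import edlib

from oncopanel.core_io import AssayConfig
from oncopanel.errors import FormatError, ParameterError

_ALLELE_RE = re.compile(
    r"^(?P<gene>HLA-[A-Z0-9]+)\*(?P<fields>\d+(?::\d+)*[A-Z]?)$"
)

AffinityPredictor = Callable[[str, str], float]


@dataclass(frozen=True)
class HlaGenotype:
    """Class I alleles in standard nomenclature (e.g. ``HLA-A*02:01``)."""

    alleles: tuple[str, ...]
    resolution: str = "four_digit"

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 6:
            raise ParameterError("expected 1-6 class I alleles")
        if self.resolution not in ("two_digit", "four_digit"):
            raise ParameterError(f"unknown resolution {self.resolution!r}")
        for a in self.alleles:
            if _ALLELE_RE.match(a) is None:
                raise FormatError(f"malformed HLA allele name {a!r}")

    @classmethod
    def from_file(cls, path: str, resolution: str = "four_digit") -> "HlaGenotype":
        with open(path) as fh:
            alleles = tuple(line.strip() for line in fh if line.strip())
        return cls(alleles=alleles, resolution=resolution)


@dataclass(frozen=True)
class MutantPeptideSet:
    """All candidate peptides covering a mutation, with mutated offsets."""

    variant_id: str
    peptides: tuple[str, ...]
    mutated_positions: tuple[frozenset[int], ...]  # 0-based, per peptide

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.mutated_positions):
            raise ParameterError("peptides and position sets differ in length")


@dataclass(frozen=True)
class AntigenicityCall:
    antigenic: bool
    best_affinity_nm: float | None = None
    best_peptide: str | None = None
    best_allele: str | None = None


def enumerate_mutant_peptides(
    protein: str,
    mutated_aa_positions: Sequence[int],
    lengths: range | None = None,
    variant_id: str = "",
) -> MutantPeptideSet:
    """All windows of each length containing >= 1 mutated residue.

    ``mutated_aa_positions`` are 1-based; windows are clipped to the
    protein bounds and duplicate peptide sequences removed (first
    occurrence kept). A protein shorter than the smallest window length
    yields an empty set.
    """
    if not mutated_aa_positions:
        raise ParameterError("empty mutated position set")
    lengths = lengths if lengths is not None else range(8, 12)
    positions0 = sorted({p - 1 for p in mutated_aa_positions})
    if positions0[0] < 0 or positions0[-1] >= len(protein):
        raise ParameterError("mutated position outside protein")
    seen: dict[str, set[int]] = {}
    ordered: list[str] = []
    for L in lengths:
        for start in range(0, len(protein) - L + 1):
            window_mut = {p - start for p in positions0 if start <= p < start + L}
            if not window_mut:
                continue
            pep = protein[start : start + L]
            if pep not in seen:
                seen[pep] = set()
                ordered.append(pep)
            seen[pep] |= window_mut
    return MutantPeptideSet(
        variant_id=variant_id,
        peptides=tuple(ordered),
        mutated_positions=tuple(frozenset(seen[p]) for p in ordered),
    )


def nearest_allele(
    query: str,
    supported: Sequence[str],
    allele_sequences: Mapping[str, str],
) -> str:
    """The supported allele with minimal binding-domain edit distance.

    Global (Needleman-Wunsch) edit distance on the provided amino-acid
    sequences; ties break lexicographically by allele name. A query that
    is itself supported is returned unchanged.
    """
    if not supported:
        raise ParameterError("empty supported allele set")
    if query in supported:
        return query
    if query not in allele_sequences:
        raise LookupError(f"no binding-domain sequence for query allele {query}")
    qseq = allele_sequences[query]
    best_name, best_dist = None, None
    for name in sorted(supported):
        if name not in allele_sequences:
            raise LookupError(f"no binding-domain sequence for allele {name}")
        dist = edlib.align(qseq, allele_sequences[name], task="distance")[
            "editDistance"
        ]
        if best_dist is None or dist < best_dist:
            best_name, best_dist = name, dist
    return best_name


def is_antigenic(
    peptides: MutantPeptideSet,
    genotype: HlaGenotype,
    predictor: AffinityPredictor,
    config: AssayConfig | None = None,
    supported_alleles: Sequence[str] | None = None,
    allele_sequences: Mapping[str, str] | None = None,
) -> AntigenicityCall:
    """Antigenic iff any peptide binds any patient allele below the cutoff.

    When ``supported_alleles`` is given, unsupported patient alleles are
    substituted by :func:`nearest_allele` before prediction (the
    prediction is attributed to the patient's allele). Strict inequality
    at the 500 nM default cutoff.
    """
    config = config or AssayConfig()
    if not peptides.peptides:
        return AntigenicityCall(antigenic=False)
    best: tuple[float, str, str] | None = None
    for allele in genotype.alleles:
        scored_allele = allele
        if supported_alleles is not None and allele not in supported_alleles:
            if allele_sequences is None:
                raise ParameterError(
                    "nearest-allele fallback requires allele_sequences"
                )
            scored_allele = nearest_allele(allele, supported_alleles, allele_sequences)
        for pep in peptides.peptides:
            nm = float(predictor(pep, scored_allele))
            if best is None or nm < best[0]:
                best = (nm, pep, allele)
    nm, pep, allele = best
    return AntigenicityCall(
        antigenic=nm < config.affinity_cutoff_nm,
        best_affinity_nm=nm,
        best_peptide=pep,
        best_allele=allele,
    )


def hla_match_at_resolution(called: str, truth: str, resolution: str) -> bool:
    """Compare two allele names truncated to allele-group or protein level.

    ``two_digit`` compares the first field only (allele group);
    ``four_digit`` the first two fields (protein).
    """
    n_fields = {"two_digit": 1, "four_digit": 2}.get(resolution)
    if n_fields is None:
        raise ParameterError(f"unknown resolution {resolution!r}")
    parsed = []
    for name in (called, truth):
        m = _ALLELE_RE.match(name)
        if m is None:
            raise FormatError(f"malformed HLA allele name {name!r}")
        fields = re.sub(r"[A-Z]$", "", m.group("fields")).split(":")
        if len(fields) < n_fields:
            raise FormatError(
                f"{name!r} has fewer than {n_fields} fields for {resolution}"
            )
        parsed.append((m.group("gene"), tuple(fields[:n_fields])))
    return parsed[0] == parsed[1]
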