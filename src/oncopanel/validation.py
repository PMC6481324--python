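"""Assay-validation statistics: concordance, VAF precision, LOD, uniformity.

The arithmetic layer behind clinical validation reporting: binary
concordance metrics (sensitivity, specificity, PPV) from TP/FP/FN/TN
counts as exact fractions and half-up rounded percentages, VAF
concordance (r^2), per-VAF-bin precision, dilution-series limit of
detection, and the coverage-uniformity QC gate (95% of targeted bases at
300x or deeper).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

import numpy as np

from oncopanel.core_io import AssayConfig
from oncopanel.errors import MetricError, ParameterError


@dataclass(frozen=True)
class ConcordanceCounts:
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MetricValue:
    """A concordance metric as an exact fraction plus display percentage."""

    fraction: Fraction
    percent: float  # half-up rounded to one decimal
    display: str  # capped at ">99.9%" when the fraction exceeds 99.9%


def round_half_up_percent(fraction: Fraction) -> float:
    """Percentage rounded half-up to one decimal (e.g. 126/130 -> 96.9)."""
    pct = Decimal(fraction.numerator * 100) / Decimal(fraction.denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _metric(numer: int, denom: int) -> MetricValue:
    frac = Fraction(numer, denom)
    pct = round_half_up_percent(frac)
    if frac > Fraction(999, 1000) and frac < 1:
        display = ">99.9%"
    else:
        display = f"{pct}%"
    return MetricValue(fraction=frac, percent=pct, display=display)


def binary_metrics(counts: ConcordanceCounts) -> dict[str, MetricValue]:
    """Sensitivity, specificity and PPV, where their denominators exist.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); ppv = tp/(tp+fp).
    A metric whose counts are missing or whose denominator is zero is
    omitted from the result.
    """
    out: dict[str, MetricValue] = {}
    c = counts
    if c.tp is not None and c.fn is not None and (c.tp + c.fn) > 0:
        out["sensitivity"] = _metric(c.tp, c.tp + c.fn)
    if c.tn is not None and c.fp is not None and (c.tn + c.fp) > 0:
        out["specificity"] = _metric(c.tn, c.tn + c.fp)
    if c.tp is not None and c.fp is not None and (c.tp + c.fp) > 0:
        out["ppv"] = _metric(c.tp, c.tp + c.fp)
    if not out:
        raise MetricError("no metric has a positive denominator")
    return out


def positions_assayed(n_samples: int, n_sites: int) -> int:
    """Specificity denominator: samples x assayed genomic sites."""
    if n_samples < 0 or n_sites < 0:
        raise ParameterError("counts must be non-negative")
    return n_samples * n_sites


def vaf_concordance(pairs: Sequence[tuple[float, float]]) -> float:
    """Squared sample correlation (r^2) of paired VAF measurements."""
    if len(pairs) < 3:
        raise ParameterError("need at least 3 VAF pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MetricError("zero variance in one coordinate; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def precision_by_vaf_bin(
    calls: Sequence[tuple[float, bool]], bin_width: float = 0.05
) -> dict[float, float]:
    """Per-bin precision with VAFs rounded to the nearest bin center.

    Bins are multiples of ``bin_width`` (nearest-5% by default; exact
    midpoints round half-up, so 0.075 joins the 0.10 bin). Empty bins are
    absent from the table.
    """
    totals: dict[float, list[int]] = {}
    for vaf, concordant in calls:
        if not 0.0 <= vaf <= 1.0:
            raise ParameterError(f"VAF {vaf} outside [0, 1]")
        k = int(
            Decimal(repr(vaf / bin_width)).quantize(
                Decimal("1"), rounding=ROUND_HALF_UP
            )
        )
        center = round(k * bin_width, 10)
        entry = totals.setdefault(center, [0, 0])
        entry[0] += bool(concordant)
        entry[1] += 1
    return {center: conc / tot for center, (conc, tot) in sorted(totals.items())}


@dataclass(frozen=True)
class DilutionSeries:
    """Detection flags along a two-fold serial dilution of known variants."""

    starting_vaf: float
    n_halvings: int
    detected: tuple[bool, ...]
    observed_vaf: tuple[float, ...]

    def __post_init__(self) -> None:
        steps = self.n_halvings + 1
        if len(self.detected) != steps or len(self.observed_vaf) != steps:
            raise ParameterError(f"series needs {steps} steps")


@dataclass(frozen=True)
class LodResult:
    lod_vaf: float | None
    expected_vafs: tuple[float, ...]
    slope: float
    intercept: float


def lod_from_dilution(series: DilutionSeries) -> LodResult:
    """Limit of detection and linearity fit of a serial dilution.

    Expected VAFs halve per step; the LOD is the smallest expected VAF
    detected with every larger step also detected (consistent detection
    down to that level). The slope fit is the least-squares line of
    observed vs expected VAF. With nothing detected the LOD is None.
    """
    if series.n_halvings + 1 < 2:
        raise ParameterError("need at least 2 dilution steps")
    expected = tuple(
        series.starting_vaf * 2.0 ** (-k) for k in range(series.n_halvings + 1)
    )
    lod = None
    for exp, det in zip(expected, series.detected):
        if det:
            lod = exp
        else:
            break
    x = np.asarray(expected)
    y = np.asarray(series.observed_vaf, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return LodResult(
        lod_vaf=lod,
        expected_vafs=expected,
        slope=float(slope),
        intercept=float(intercept),
    )


def coverage_uniformity(
    depths: Sequence[float], config: AssayConfig | None = None
) -> tuple[float, bool]:
    """Fraction of positions at or above the minimum depth, and the QC gate.

    Passes when at least 95% of targeted positions reach 300x (both
    bounds inclusive, both configurable).
    """
    config = config or AssayConfig()
    if len(depths) == 0:
        raise ParameterError("empty depth list")
    d = np.asarray(depths, dtype=float)
    fraction = float(np.mean(d >= config.uniformity_depth))
    return fraction, fraction >= config.uniformity_fraction
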