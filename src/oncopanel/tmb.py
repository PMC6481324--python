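"""Tumor mutational burden scoring and threshold calibration.

TMB is the count of non-silent somatic coding mutations passing the
evidence filters (coverage strictly above 100x, allele fraction strictly
above 5%) divided by the panel footprint in megabases (2.4 Mb by
default). Burden strictly above 9 mutations/Mb is classified high. The
threshold itself can be re-derived on a cohort by hypergeometric testing
for enrichment of orthogonally defined hypermutation (MSI-H) among
samples above each candidate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from oncopanel.core_io import AssayConfig, VariantRecord
from oncopanel.errors import ParameterError, TrainingError

NON_SILENT = frozenset(
    {"missense", "nonsense", "stop_loss", "frameshift_indel", "inframe_indel"}
)


@dataclass(frozen=True)
class TmbResult:
    n_counted: int
    panel_mb: float
    tmb: float
    high: bool


def passes_tmb_filters(v: VariantRecord, config: AssayConfig | None = None) -> bool:
    """Somatic, non-silent coding, depth > 100x and VAF > 5% (all strict)."""
    config = config or AssayConfig()
    return (
        v.origin == "somatic"
        and v.consequence in NON_SILENT
        and v.depth > config.tmb_min_depth
        and v.vaf > config.tmb_min_vaf
    )


def compute_tmb(
    variants: Sequence[VariantRecord], config: AssayConfig | None = None
) -> TmbResult:
    """Mutations per megabase over the panel; high iff strictly above threshold."""
    config = config or AssayConfig()
    if config.panel_megabases <= 0:
        raise ParameterError("panel_megabases must be positive")
    n = sum(passes_tmb_filters(v, config) for v in variants)
    tmb = n / config.panel_megabases
    return TmbResult(
        n_counted=n,
        panel_mb=config.panel_megabases,
        tmb=tmb,
        high=tmb > config.tmb_high_threshold,
    )


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts successes when drawing ``n`` items without replacement from
    a population of ``N`` containing ``K`` successes. Computed by exact
    log-space summation of the PMF over the upper tail.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ParameterError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    upper = min(K, n)
    xs = np.arange(k, upper + 1)
    logpmf = stats.hypergeom.logpmf(xs, N, K, n)
    return float(min(1.0, np.exp(_logsumexp(logpmf))))


def _logsumexp(logs: np.ndarray) -> float:
    m = float(np.max(logs))
    return m + float(np.log(np.sum(np.exp(logs - m))))


def calibrate_threshold(
    tmb_values: Sequence[float],
    msih_flags: Sequence[bool],
    grid: Sequence[float],
) -> tuple[float, dict[float, float]]:
    """Pick the TMB threshold maximizing MSI-H enrichment above it.

    For each candidate t: k = MSI-H samples with tmb > t, n = samples
    with tmb > t, K = all MSI-H, N = cohort size; the enrichment p-value
    is the upper-tail hypergeometric. Returns the candidate with minimal
    p (ties broken toward the smallest threshold) and the full
    per-candidate table. A candidate with nothing above it gets p = 1.
    """
    if len(tmb_values) != len(msih_flags):
        raise ParameterError("tmb_values and msih_flags differ in length")
    if not grid:
        raise ParameterError("empty threshold grid")
    K = int(sum(bool(f) for f in msih_flags))
    if K == 0:
        raise TrainingError("no MSI-H samples in the calibration cohort")
    N = len(tmb_values)
    table: dict[float, float] = {}
    for t in grid:
        above = [(v, f) for v, f in zip(tmb_values, msih_flags) if v > t]
        n = len(above)
        k = sum(bool(f) for _, f in above)
        table[float(t)] = 1.0 if n == 0 else hypergeometric_enrichment(k, K, n, N)
    best = min(table, key=lambda t: (table[t], t))
    return best, table
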