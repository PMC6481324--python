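"""Copy-number analysis from per-target depths and het-SNV allele fractions.

The pipeline: tumor/normal depth ratios are scaled, log2-transformed and
median-centered; circular binary segmentation (CBS) with permutation-based
split acceptance partitions the target list into segments of constant
copy ratio; a purity x ploidy grid search fits observed segment ratios
and B-allele-fraction deviations to the nearest integer copy states under
the stromal-admixture mixture model

    expected_ratio(c) = (p*c + 2*(1 - p)) / (p*psi + 2*(1 - p)),

and each segment then receives the integer copy number minimizing the
distance to its observed ratio. Focal amplifications are called at a
copy-ratio of 2.5 and arm-level gains/losses when 80% of an arm's covered
length departs from CN 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from oncopanel.core_io import (
    AssayConfig,
    GenomicInterval,
    HetSnvObservation,
    TargetCoverage,
    get_logger,
)
from oncopanel.errors import ParameterError

_log = get_logger("cnv")

_MAX_CN = 12


@dataclass(frozen=True)
class CopyNumberSegment:
    """A run of targets with a common copy ratio."""

    interval: GenomicInterval
    n_targets: int
    log2_ratio: float
    mean_baf_deviation: float = float("nan")
    integer_cn: int | None = None

    @property
    def ratio(self) -> float:
        return float(2.0**self.log2_ratio)


@dataclass(frozen=True)
class PurityPloidyFit:
    purity: float
    ploidy: float
    goodness_of_fit: float
    penalty: float

    @property
    def total_score(self) -> float:
        return self.goodness_of_fit + self.penalty


# ---------------------------------------------------------------------------
# Log ratios
# ---------------------------------------------------------------------------


def compute_log_ratios(
    targets: list[TargetCoverage],
    pool: list[float] | None = None,
    gc_correct: bool = False,
) -> tuple[list[TargetCoverage], np.ndarray]:
    """Median-centered log2 tumor/comparator depth ratios per target.

    The comparator is the matched normal, or ``pool`` (per-target pooled
    normal depths) in tumor-only mode. Both depth vectors are scaled to
    equal totals before the ratio so library size cancels. Targets with a
    zero comparator depth are dropped with a warning. Optional GC
    correction subtracts the median log ratio of each GC decile.
    """
    if not targets:
        raise ParameterError("no coverage targets")
    if pool is not None and len(pool) != len(targets):
        raise ParameterError("pool depth vector length mismatch")
    comparator = (
        np.asarray(pool, dtype=float)
        if pool is not None
        else np.asarray([t.normal_depth for t in targets], dtype=float)
    )
    tumor = np.asarray([t.tumor_depth for t in targets], dtype=float)
    keep = comparator > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        _log.warning("dropping %d targets with zero comparator depth", n_dropped)
    kept = [t for t, k in zip(targets, keep) if k]
    tumor, comparator = tumor[keep], comparator[keep]
    if tumor.sum() <= 0:
        raise ParameterError("tumor depth is zero everywhere")
    scale = comparator.sum() / tumor.sum()
    with np.errstate(divide="ignore"):
        log2r = np.log2(tumor * scale) - np.log2(comparator)
    log2r = log2r - np.median(log2r)
    if gc_correct:
        gc = np.asarray(
            [t.gc_fraction if t.gc_fraction is not None else np.nan for t in kept]
        )
        if np.isnan(gc).any():
            raise ParameterError("gc_correct requires gc_fraction on every target")
        deciles = np.clip((gc * 10).astype(int), 0, 9)
        for d in np.unique(deciles):
            mask = deciles == d
            log2r[mask] = log2r[mask] - np.median(log2r[mask])
        log2r = log2r - np.median(log2r)
    return kept, log2r


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------


def _arc_indices(n: int, min_width: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) pairs over cumsum indices with arc and complement >= min_width."""
    i, j = np.triu_indices(n + 1, k=min_width)
    keep = (j - i >= min_width) & (n - (j - i) >= min_width)
    return i[keep], j[keep]


def _max_arc_t(x: np.ndarray, i: np.ndarray, j: np.ndarray) -> tuple[float, int, int]:
    """Maximum |t| over circular arcs x[i:j] vs the complement."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    k = (j - i).astype(float)
    arc = s[j] - s[i]
    rest = s[-1] - arc
    m = n - k
    mean_diff = arc / k - rest / m
    ss = s2[-1] - (arc**2) / k - (rest**2) / m
    df = max(n - 2, 1)
    sd = np.sqrt(np.maximum(ss / df, 1e-300))
    t = np.abs(mean_diff) / (sd * np.sqrt(1.0 / k + 1.0 / m))
    best = int(np.argmax(t))
    return float(t[best]), int(i[best]), int(j[best])


def _split_p_value(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, int, int]:
    """Permutation p-value of the best circular split of ``x``.

    Early-stops once enough permuted maxima exceed the observed one for
    the final p-value to be guaranteed above alpha (the usual sequential
    shortcut: it changes no accept/reject decision).
    """
    n = len(x)
    i, j = _arc_indices(n)
    t_obs, bi, bj = _max_arc_t(x, i, j)
    stop_at = int(np.ceil(alpha * (n_perm + 1)))
    exceed = 0
    done = 0
    while done < n_perm:
        t_perm, _, _ = _max_arc_t(rng.permutation(x), i, j)
        exceed += t_perm >= t_obs
        done += 1
        if exceed >= stop_at:
            break
    p = (exceed + 1) / (done + 1)
    return p, bi, bj


def cbs_segment(
    targets: list[TargetCoverage],
    log2_ratios: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    merge_tolerance: float = 0.1,
) -> list[CopyNumberSegment]:
    """Segment ordered per-target log2 ratios by circular binary segmentation.

    Recursively accepts the arc maximizing the circular two-sample
    t-statistic whenever its seeded permutation p-value is below
    ``alpha``; adjacent segments whose means differ by less than
    ``merge_tolerance`` log2 units are re-merged afterward. Targets must
    be sorted by genome position; chromosomes are segmented independently.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha {alpha} outside (0, 1)")
    x = np.asarray(log2_ratios, dtype=float)
    if len(x) != len(targets):
        raise ParameterError("ratio vector length mismatch")
    rng = np.random.default_rng(seed)

    segments: list[CopyNumberSegment] = []
    chroms = [t.interval.chrom for t in targets]
    start_idx = 0
    for idx in range(1, len(targets) + 1):
        if idx == len(targets) or chroms[idx] != chroms[start_idx]:
            bounds = _segment_chromosome(
                x[start_idx:idx], alpha, n_perm, rng
            )
            bounds = _merge_close(x[start_idx:idx], bounds, merge_tolerance)
            for a, b in bounds:
                seg_targets = targets[start_idx + a : start_idx + b]
                segments.append(
                    CopyNumberSegment(
                        interval=GenomicInterval(
                            seg_targets[0].interval.chrom,
                            seg_targets[0].interval.start,
                            seg_targets[-1].interval.end,
                        ),
                        n_targets=b - a,
                        log2_ratio=float(np.mean(x[start_idx + a : start_idx + b])),
                    )
                )
            start_idx = idx
    return segments


def _segment_chromosome(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n = len(x)
    if n < 4:  # too short for an arc and complement of width >= 2
        return [(0, n)] if n else []
    if np.allclose(x, x[0]):
        return [(0, n)]
    p, i, j = _split_p_value(x, alpha, n_perm, rng)
    if p >= alpha:
        return [(0, n)]
    pieces = [(0, i), (i, j), (j, n)]
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        if b - a == 0:
            continue
        sub = _segment_chromosome(x[a:b], alpha, n_perm, rng)
        out.extend((a + s, a + e) for s, e in sub)
    return out


def _merge_close(
    x: np.ndarray, bounds: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    merged = list(bounds)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for k in range(len(merged) - 1):
            a, b = merged[k]
            b2, c = merged[k + 1]
            if abs(np.mean(x[a:b]) - np.mean(x[b2:c])) < tol:
                merged[k : k + 2] = [(a, c)]
                changed = True
                break
    return merged


# ---------------------------------------------------------------------------
# Purity / ploidy fitting
# ---------------------------------------------------------------------------


def attach_baf(
    segments: list[CopyNumberSegment], het_snvs: list[HetSnvObservation]
) -> list[CopyNumberSegment]:
    """Fill each segment's mean |alt fraction - 0.5| from overlapping SNVs."""
    out = []
    for seg in segments:
        devs = [
            abs(s.tumor_alt_fraction - 0.5)
            for s in het_snvs
            if seg.interval.overlaps(s.interval)
        ]
        out.append(
            replace(
                seg,
                mean_baf_deviation=float(np.mean(devs)) if devs else float("nan"),
            )
        )
    return out


def _expected_ratio(c: np.ndarray, purity: float, ploidy: float) -> np.ndarray:
    denom = purity * ploidy + 2.0 * (1.0 - purity)
    return (purity * c + 2.0 * (1.0 - purity)) / denom


def _expected_baf_dev(c: int, purity: float) -> np.ndarray:
    """Expected |BAF - 0.5| for each allelic configuration of CN ``c``."""
    total = purity * c + 2.0 * (1.0 - purity)
    alts = np.arange(0, c + 1)
    if total <= 0:  # homozygous deletion in a pure tumor: no reads
        return np.asarray([0.0])
    return np.abs((purity * alts + (1.0 - purity)) / total - 0.5)


def default_grid() -> list[tuple[float, float]]:
    """Purity 0.05-1.00 (step 0.01) x ploidy 1.5-5.0 (step 0.1)."""
    purities = np.round(np.arange(0.05, 1.0001, 0.01), 2)
    ploidies = np.round(np.arange(1.5, 5.0001, 0.1), 1)
    return [(float(p), float(q)) for p in purities for q in ploidies]


def estimate_purity_ploidy(
    segments: list[CopyNumberSegment],
    het_snvs: list[HetSnvObservation] | None = None,
    grid: list[tuple[float, float]] | None = None,
    baf_weight: float = 1.0,
    ploidy_penalty: float = 0.1,
    integer_penalty: float = 0.1,
    aberration_penalty: float = 0.002,
) -> PurityPloidyFit:
    """Grid search for the (purity, ploidy) model explaining the segments.

    Each candidate scores the target-weighted squared distance of
    observed (ratio, BAF deviation) to the nearest integer copy state
    under the mixture model. The penalty prefers near-diploid genome-wide
    ploidy, near-integer average ploidy, and the least-aberrant copy
    assignment — which also breaks the intrinsic degeneracy between
    high-purity/low-CN and low-purity/high-CN explanations of the same
    ratio toward the more parsimonious one.
    """
    if not segments:
        raise ParameterError("no segments to fit")
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ParameterError("empty purity/ploidy grid")
    if het_snvs is not None:
        segments = attach_baf(segments, het_snvs)
    ratios = np.asarray([s.ratio for s in segments])
    bafs = np.asarray([s.mean_baf_deviation for s in segments])
    weights = np.asarray([s.n_targets for s in segments], dtype=float)
    weights = weights / weights.sum()
    cn_states = np.arange(0, _MAX_CN + 1)

    best: PurityPloidyFit | None = None
    has_baf = np.isfinite(bafs)
    baf_cache: dict[float, np.ndarray] = {}
    for purity, ploidy in grid:
        exp_ratio = _expected_ratio(cn_states, purity, ploidy)
        if purity not in baf_cache:
            # d_baf[s, c]: distance of each segment's BAF deviation to the
            # nearest allelic configuration of copy state c at this purity
            dev_pad = np.full((len(cn_states), _MAX_CN + 1), np.inf)
            for ci, c in enumerate(cn_states):
                devs = _expected_baf_dev(int(c), purity)
                dev_pad[ci, : len(devs)] = devs
            diffs = (bafs[:, None, None] - dev_pad[None, :, :]) ** 2
            d_baf = np.min(np.where(np.isfinite(dev_pad), diffs, np.inf), axis=2)
            d_baf[~has_baf] = 0.0
            baf_cache[purity] = np.nan_to_num(d_baf, nan=0.0)
        d_ratio = (ratios[:, None] - exp_ratio[None, :]) ** 2
        dist = d_ratio + baf_weight * baf_cache[purity]
        c_best = np.argmin(dist, axis=1)  # argmin takes the smaller c on ties
        assigned = cn_states[c_best].astype(float)
        goodness = float(np.sum(weights * dist[np.arange(len(segments)), c_best]))
        # genome-wide ploidy state: the target-weighted median copy number,
        # robust to focal events that would make a weighted mean non-integer
        order = np.argsort(assigned)
        cum = np.cumsum(weights[order])
        fitted_ploidy = float(assigned[order][np.searchsorted(cum, 0.5)])
        penalty = (
            ploidy_penalty * abs(ploidy - 2.0)
            + integer_penalty * abs(fitted_ploidy - round(fitted_ploidy))
            + aberration_penalty * float(np.sum(weights * np.abs(assigned - 2)))
        )
        fit = PurityPloidyFit(
            purity=purity, ploidy=ploidy, goodness_of_fit=goodness, penalty=penalty
        )
        if (
            best is None
            or fit.total_score < best.total_score - 1e-12
            or (
                abs(fit.total_score - best.total_score) <= 1e-12
                and (abs(ploidy - 2.0), -purity)
                < (abs(best.ploidy - 2.0), -best.purity)
            )
        ):
            best = fit
    return best


def assign_integer_cn(
    segments: list[CopyNumberSegment], fit: PurityPloidyFit
) -> list[CopyNumberSegment]:
    """Give each segment the integer copy number nearest its observed ratio."""
    cn_states = np.arange(0, _MAX_CN + 1)
    exp_ratio = _expected_ratio(cn_states, fit.purity, fit.ploidy)
    out = []
    for seg in segments:
        c = int(cn_states[np.argmin(np.abs(seg.ratio - exp_ratio))])
        out.append(replace(seg, integer_cn=c))
    return out


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------


def call_focal_amplification(ratio: float, config: AssayConfig | None = None) -> bool:
    """Amplified at or above the 2.5 copy-ratio boundary (inclusive)."""
    config = config or AssayConfig()
    return ratio >= config.amplification_ratio


def gene_level_ratios(
    targets: list[TargetCoverage], log2_ratios: np.ndarray
) -> dict[str, float]:
    """Mean copy ratio (2^mean log2) per gene across its targets."""
    sums: dict[str, list[float]] = {}
    for t, lr in zip(targets, log2_ratios):
        sums.setdefault(t.gene, []).append(float(lr))
    return {g: float(2.0 ** np.mean(v)) for g, v in sums.items()}


def call_arm_events(
    segments: list[CopyNumberSegment],
    arm_table: list[tuple[str, GenomicInterval]],
    config: AssayConfig | None = None,
) -> dict[str, str]:
    """Per-arm loss/neutral/gain from integer copy numbers.

    An arm is lost when >= 80% (``arm_event_fraction``) of its covered
    length sits in segments with CN < 2, gained when >= 80% has CN > 2.
    Arms without any covered segment are omitted (logged).
    """
    config = config or AssayConfig()
    out: dict[str, str] = {}
    for arm_name, arm in arm_table:
        covered = loss = gain = 0
        for seg in segments:
            if seg.integer_cn is None:
                raise ParameterError("arm calling requires fitted integer CN")
            if not seg.interval.overlaps(arm):
                continue
            length = min(seg.interval.end, arm.end) - max(seg.interval.start, arm.start)
            covered += length
            if seg.integer_cn < 2:
                loss += length
            elif seg.integer_cn > 2:
                gain += length
        if covered == 0:
            _log.info("arm %s has no covered targets; no call", arm_name)
            continue
        if loss / covered >= config.arm_event_fraction:
            out[arm_name] = "loss"
        elif gain / covered >= config.arm_event_fraction:
            out[arm_name] = "gain"
        else:
            out[arm_name] = "neutral"
    return out
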