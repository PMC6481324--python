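"""Microsatellite-instability classification from repeat-length histograms.

Paired tumor-normal mode tests each microsatellite locus for a change in
the repeat-length distribution between tumor and normal reads with a
two-sample Kolmogorov-Smirnov test (a locus is unstable at p <= 0.05) and
feeds the proportion of unstable loci into a logistic classifier that
returns the probability of MSI-H. Tumor-only mode summarizes each locus
by the read-weighted mean and variance of repeat length and scores the
vector with a calibrated linear support-vector classifier. Both modes
report MSI-H above 70% probability, MSS below 30%, and the equivocal
class MSE in between; samples with fewer than 20 usable loci fail QC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import special
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from oncopanel.core_io import AssayConfig, MicrosatelliteLocusProfile
from oncopanel.errors import (
    EvidenceError,
    FormatError,
    ModelError,
    TrainingError,
)

STATUS_MSIH = "MSI-H"
STATUS_MSS = "MSS"
STATUS_MSE = "MSE"
STATUS_QC_FAIL = "QC_FAIL"


@dataclass(frozen=True)
class LocusTestResult:
    locus_id: str
    usable: bool
    ks_statistic: float = float("nan")
    p_value: float = float("nan")
    unstable: bool = False


@dataclass(frozen=True)
class MsiCall:
    """Outcome of MSI classification for one specimen."""

    mode: str  # paired | tumor_only
    n_usable_loci: int
    status: str
    probability_msih: float | None = None
    proportion_unstable: float | None = None


@dataclass(frozen=True)
class MsiClassifierModel:
    """Serializable classifier parameters.

    ``logistic_proportion``: parameters = [intercept, slope] on the
    unstable-locus proportion. ``margin_mean_variance``: parameters =
    [intercept, w_1..w_2k] on the per-locus (mean, variance) layout, with
    ``calibration`` = (A, B) of a sigmoid p = 1/(1 + exp(A*margin + B))
    fitted on held-out folds.
    """

    kind: str
    parameters: tuple[float, ...]
    calibration: tuple[float, ...] = ()
    feature_layout: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("logistic_proportion", "margin_mean_variance"):
            raise ModelError(f"unknown model kind {self.kind!r}")
        if self.kind == "logistic_proportion" and len(self.parameters) != 2:
            raise ModelError("logistic_proportion expects [intercept, slope]")
        if self.kind == "margin_mean_variance":
            expected = 1 + 2 * len(self.feature_layout)
            if len(self.parameters) != expected:
                raise ModelError(
                    f"margin model expects {expected} parameters for "
                    f"{len(self.feature_layout)} loci, got {len(self.parameters)}"
                )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "parameters": list(self.parameters),
                    "calibration": list(self.calibration),
                    "feature_layout": list(self.feature_layout),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "MsiClassifierModel":
        with open(path) as fh:
            doc = json.load(fh)
        try:
            return cls(
                kind=doc["kind"],
                parameters=tuple(doc["parameters"]),
                calibration=tuple(doc.get("calibration", ())),
                feature_layout=tuple(doc.get("feature_layout", ())),
            )
        except KeyError as exc:
            raise FormatError(f"{path}: missing model key {exc}") from exc


# ---------------------------------------------------------------------------
# Locus-level evidence
# ---------------------------------------------------------------------------


def locus_qc(
    profile: MicrosatelliteLocusProfile,
    config: AssayConfig | None = None,
    paired: bool = True,
) -> bool:
    """A locus is usable with >= 30 reads in tumor (and normal, if paired)
    and flank-qualified read mapping."""
    config = config or AssayConfig()
    if not profile.flank_ok:
        return False
    if profile.tumor_reads < config.msi_min_locus_reads:
        return False
    if paired and profile.normal_reads < config.msi_min_locus_reads:
        return False
    return True


def _weighted_ecdf_gap(
    tumor_hist: dict[int, int], normal_hist: dict[int, int]
) -> tuple[float, int, int]:
    support = sorted(set(tumor_hist) | set(normal_hist))
    t = np.asarray([tumor_hist.get(k, 0) for k in support], dtype=float)
    u = np.asarray([normal_hist.get(k, 0) for k in support], dtype=float)
    n, m = t.sum(), u.sum()
    gap = np.abs(np.cumsum(t) / n - np.cumsum(u) / m)
    return float(gap.max()), int(n), int(m)


def _exact_ks_permutation_p(
    tumor_hist: dict[int, int], normal_hist: dict[int, int], d_obs: float
) -> float:
    """Exact P(D >= d_obs) over all relabelings of the pooled reads.

    Repeat-length read data are heavily tied, so the continuous-sample
    asymptotic Kolmogorov distribution is badly conservative here.
    Instead the permutation null is computed exactly by a ballot-path
    dynamic program: weight W(t_1..t_k) = prod C(c_i, t_i) over tables of
    tumor counts per length bin, summed over tables whose every ECDF
    prefix gap stays strictly below d_obs, and complemented. Runs in
    O(k * n * max c_i) via convolutions; fully deterministic.
    """
    support = sorted(set(tumor_hist) | set(normal_hist))
    c = np.asarray(
        [tumor_hist.get(v, 0) + normal_hist.get(v, 0) for v in support], dtype=int
    )
    n = sum(tumor_hist.values())
    m = sum(normal_hist.values())
    N = n + m
    if d_obs <= 0.0:
        return 1.0
    w = np.zeros(n + 1)
    w[0] = 1.0
    log_scale = 0.0
    prefix = 0
    for ci in np.asarray(c):
        binom_row = np.exp(
            special.gammaln(ci + 1)
            - special.gammaln(np.arange(ci + 1) + 1)
            - special.gammaln(ci - np.arange(ci + 1) + 1)
        )
        w = np.convolve(w, binom_row)[: n + 1]
        prefix += int(ci)
        ct = np.arange(n + 1)
        gap = np.abs(ct / n - (prefix - ct) / m)
        # infeasible states (more tumor reads than seen, or than n) carry
        # zero weight already; kill states whose prefix gap reaches d_obs
        w[gap >= d_obs - 1e-12] = 0.0
        top = w.max()
        if top == 0.0:
            return 1.0  # every table exceeds the band: P(D >= d_obs) = 1
        w /= top
        log_scale += np.log(top)
    if w[n] == 0.0:  # no in-band table has the right tumor total
        return 1.0
    log_in_band = np.log(w[n]) + log_scale
    log_total = (
        special.gammaln(N + 1) - special.gammaln(n + 1) - special.gammaln(m + 1)
    )
    p = 1.0 - float(np.exp(log_in_band - log_total))
    return float(min(1.0, max(p, 1e-16)))


def ks_instability_test(
    tumor_hist: dict[int, int],
    normal_hist: dict[int, int],
    cutoff: float = 0.05,
    locus_id: str = "",
) -> LocusTestResult:
    """Two-sample KS test on read-weighted repeat-length distributions.

    D is the maximum gap between the two read-weighted empirical CDFs;
    the p-value is the exact permutation tail P(D >= d) over relabelings
    of the pooled reads (see :func:`_exact_ks_permutation_p`), which
    handles the ties inherent to repeat-length histograms. The locus is
    unstable when p <= cutoff.
    """
    if not tumor_hist or sum(tumor_hist.values()) == 0:
        raise EvidenceError(f"locus {locus_id}: empty tumor histogram")
    if not normal_hist or sum(normal_hist.values()) == 0:
        raise EvidenceError(f"locus {locus_id}: empty normal histogram")
    d, n, m = _weighted_ecdf_gap(tumor_hist, normal_hist)
    p = _exact_ks_permutation_p(tumor_hist, normal_hist, d)
    return LocusTestResult(
        locus_id=locus_id,
        usable=True,
        ks_statistic=d,
        p_value=p,
        unstable=p <= cutoff,
    )


def test_loci(
    profiles: list[MicrosatelliteLocusProfile], config: AssayConfig | None = None
) -> list[LocusTestResult]:
    """Run locus QC and the KS instability test across the panel."""
    config = config or AssayConfig()
    results = []
    for p in profiles:
        if p.normal_hist is None:
            raise EvidenceError(f"locus {p.locus_id}: paired mode needs a normal")
        if not locus_qc(p, config, paired=True):
            results.append(LocusTestResult(locus_id=p.locus_id, usable=False))
            continue
        results.append(
            ks_instability_test(
                dict(p.tumor_hist),
                dict(p.normal_hist),
                cutoff=config.msi_locus_p_cutoff,
                locus_id=p.locus_id,
            )
        )
    return results


def unstable_proportion(
    results: list[LocusTestResult], config: AssayConfig | None = None
) -> tuple[float, int]:
    """Proportion of usable loci that are unstable, plus the usable count."""
    if not results:
        raise EvidenceError("no locus results")
    usable = [r for r in results if r.usable]
    if not usable:
        raise EvidenceError("zero usable loci")
    n_unstable = sum(r.unstable for r in usable)
    return n_unstable / len(usable), len(usable)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _band_status(probability: float, config: AssayConfig) -> str:
    if probability > config.msi_prob_high:
        return STATUS_MSIH
    if probability < config.msi_prob_low:
        return STATUS_MSS
    return STATUS_MSE


def classify_paired(
    proportion: float,
    n_usable: int,
    model: MsiClassifierModel,
    config: AssayConfig | None = None,
) -> MsiCall:
    """Map the unstable-locus proportion to MSI status via the logistic model."""
    config = config or AssayConfig()
    if model.kind != "logistic_proportion":
        raise ModelError(f"paired mode needs logistic_proportion, got {model.kind}")
    if n_usable < config.msi_min_loci:
        return MsiCall(
            mode="paired", n_usable_loci=n_usable, status=STATUS_QC_FAIL
        )
    b0, b1 = model.parameters
    prob = float(special.expit(b0 + b1 * proportion))
    return MsiCall(
        mode="paired",
        n_usable_loci=n_usable,
        status=_band_status(prob, config),
        probability_msih=prob,
        proportion_unstable=proportion,
    )


def call_paired(
    profiles: list[MicrosatelliteLocusProfile],
    model: MsiClassifierModel,
    config: AssayConfig | None = None,
) -> MsiCall:
    """End-to-end paired-mode call: QC, per-locus KS tests, classification."""
    config = config or AssayConfig()
    results = test_loci(profiles, config)
    usable = [r for r in results if r.usable]
    if len(usable) < config.msi_min_loci:
        return MsiCall(
            mode="paired", n_usable_loci=len(usable), status=STATUS_QC_FAIL
        )
    proportion, n_usable = unstable_proportion(results, config)
    return classify_paired(proportion, n_usable, model, config)


def featurize_tumor_only(
    profiles: list[MicrosatelliteLocusProfile],
    layout: tuple[str, ...],
    config: AssayConfig | None = None,
    imputation: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, int]:
    """Read-weighted (mean, variance) of repeat length per panel locus.

    Returns a vector ordered by ``layout`` — [(mean_1, var_1), ...] —
    plus the usable-locus count. Unusable or missing loci are imputed
    with training-cohort per-locus feature means (``imputation``), which
    keeps the feature length fixed; without an imputation table they are
    filled with the locus's reference repeat count and zero variance.
    """
    config = config or AssayConfig()
    by_id = {p.locus_id: p for p in profiles}
    features = np.zeros(2 * len(layout))
    n_usable = 0
    any_usable = False
    for j, locus_id in enumerate(layout):
        profile = by_id.get(locus_id)
        usable = profile is not None and locus_qc(profile, config, paired=False)
        if usable:
            any_usable = True
            n_usable += 1
            lengths = np.asarray(sorted(profile.tumor_hist), dtype=float)
            counts = np.asarray(
                [profile.tumor_hist[int(k)] for k in lengths], dtype=float
            )
            mean = float(np.average(lengths, weights=counts))
            var = float(np.average((lengths - mean) ** 2, weights=counts))
        elif imputation and locus_id in imputation:
            mean, var = imputation[locus_id]
        else:
            ref = profile.ref_repeats if profile is not None else 0
            mean, var = float(ref), 0.0
        features[2 * j] = mean
        features[2 * j + 1] = var
    if not any_usable:
        raise EvidenceError("all loci unusable in tumor-only featurization")
    return features, n_usable


def classify_tumor_only(
    features: np.ndarray,
    n_usable: int,
    model: MsiClassifierModel,
    config: AssayConfig | None = None,
) -> MsiCall:
    """Score the (mean, variance) vector with the calibrated margin model."""
    config = config or AssayConfig()
    if model.kind != "margin_mean_variance":
        raise ModelError(
            f"tumor-only mode needs margin_mean_variance, got {model.kind}"
        )
    expected = 2 * len(model.feature_layout)
    if len(features) != expected:
        raise ModelError(f"expected {expected} features, got {len(features)}")
    if n_usable < config.msi_min_loci:
        return MsiCall(
            mode="tumor_only", n_usable_loci=n_usable, status=STATUS_QC_FAIL
        )
    intercept = model.parameters[0]
    weights = np.asarray(model.parameters[1:])
    margin = float(intercept + weights @ np.asarray(features, dtype=float))
    a, b = model.calibration if model.calibration else (-1.0, 0.0)
    prob = float(special.expit(-(a * margin + b)))
    return MsiCall(
        mode="tumor_only",
        n_usable_loci=n_usable,
        status=_band_status(prob, config),
        probability_msih=prob,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_paired_classifier(
    labeled: list[tuple[float, str]],
) -> MsiClassifierModel:
    """Maximum-likelihood logistic fit of MSI-H status on unstable proportion."""
    if not labeled:
        raise TrainingError("empty training set")
    x = np.asarray([[p] for p, _ in labeled], dtype=float)
    y = np.asarray([1 if s == STATUS_MSIH else 0 for _, s in labeled])
    if len(set(y.tolist())) < 2:
        raise TrainingError("both classes required to train")
    clf = LogisticRegression(C=np.inf, tol=1e-8, max_iter=10_000)
    clf.fit(x, y)
    return MsiClassifierModel(
        kind="logistic_proportion",
        parameters=(float(clf.intercept_[0]), float(clf.coef_[0][0])),
    )


def train_tumor_only_classifier(
    labeled: list[tuple[np.ndarray, str]],
    layout: tuple[str, ...],
    seed: int = 0,
) -> MsiClassifierModel:
    """Linear-kernel maximum-margin fit with fold-based Platt calibration.

    Uses a linear SVC with cross-validated sigmoid calibration of the
    margin; the stored model is the hyperplane plus the (A, B) sigmoid,
    so scoring needs no fitted estimator object.
    """
    if not labeled:
        raise TrainingError("empty training set")
    x = np.asarray([np.asarray(f, dtype=float) for f, _ in labeled])
    y = np.asarray([1 if s == STATUS_MSIH else 0 for _, s in labeled])
    if len(set(y.tolist())) < 2:
        raise TrainingError("both classes required to train")
    if x.shape[1] != 2 * len(layout):
        raise TrainingError(
            f"feature length {x.shape[1]} does not match layout of {len(layout)} loci"
        )
    base = SVC(kernel="linear", random_state=seed)
    calibrated = CalibratedClassifierCV(base, method="sigmoid", ensemble=False, cv=5)
    calibrated.fit(x, y)
    fitted = calibrated.calibrated_classifiers_[0]
    svm = fitted.estimator
    sigmoid = fitted.calibrators[0]
    return MsiClassifierModel(
        kind="margin_mean_variance",
        parameters=(float(svm.intercept_[0]), *map(float, svm.coef_[0])),
        calibration=(float(sigmoid.a_), float(sigmoid.b_)),
        feature_layout=tuple(layout),
    )


def train_on_simulated_cohort(
    mode: str = "paired",
    n_per_class: int = 50,
    depth_mean: float = 200.0,
    seed: int = 0,
    config: AssayConfig | None = None,
) -> MsiClassifierModel:
    """Train either classifier on a simulated labeled cohort.

    The cohort is balanced MSI-H/MSS at full purity. Clinically labeled
    training cohorts are not redistributable, so the shipped models are
    reproducible functions of a seed instead.
    """
    from oncopanel import synthetic as syn

    config = config or AssayConfig()
    layout = tuple(l for l, _, _ in syn._panel_layout(43))
    labeled_prop: list[tuple[float, str]] = []
    labeled_feat: list[tuple[np.ndarray, str]] = []
    for i in range(2 * n_per_class):
        status = STATUS_MSIH if i < n_per_class else STATUS_MSS
        sim = syn.simulate_msi_profiles(
            syn.SimulationSpec(seed=seed + i, status=status, depth_mean=depth_mean)
        )
        if mode == "paired":
            prop, _ = unstable_proportion(test_loci(list(sim.profiles), config))
            labeled_prop.append((prop, status))
        else:
            feats, _ = featurize_tumor_only(list(sim.profiles), layout, config)
            labeled_feat.append((feats, status))
    if mode == "paired":
        return train_paired_classifier(labeled_prop)
    return train_tumor_only_classifier(labeled_feat, layout, seed=seed)


def imputation_table(
    cohort: list[list[MicrosatelliteLocusProfile]],
    layout: tuple[str, ...],
    config: AssayConfig | None = None,
) -> dict[str, tuple[float, float]]:
    """Training-cohort per-locus mean feature values, for imputation."""
    config = config or AssayConfig()
    sums: dict[str, list[float]] = {k: [0.0, 0.0, 0.0] for k in layout}
    for profiles in cohort:
        features, _ = featurize_tumor_only(profiles, layout, config)
        for j, locus_id in enumerate(layout):
            sums[locus_id][0] += features[2 * j]
            sums[locus_id][1] += features[2 * j + 1]
            sums[locus_id][2] += 1.0
    return {
        k: (v[0] / v[2], v[1] / v[2]) for k, v in sums.items() if v[2] > 0
    }
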