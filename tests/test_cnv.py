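"""Log ratios, CBS, purity/ploidy fitting, integer CN, and event calls."""

import numpy as np
import pytest

from oncopanel import cnv
from oncopanel import synthetic as syn
from oncopanel.core_io import AssayConfig, GenomicInterval, TargetCoverage
from oncopanel.errors import ParameterError


def make_targets(n, chrom="1", depth=500.0, genes=None):
    out = []
    for i in range(n):
        out.append(
            TargetCoverage(
                interval=GenomicInterval(chrom, 1000 * i, 1000 * i + 200),
                gene=genes[i] if genes else f"G{i // 4}",
                tumor_depth=depth,
                normal_depth=depth,
            )
        )
    return out


def single_changepoint_oracle(x):
    """Exhaustive best single split k of x[:k] | x[k:] by two-sample t."""
    best_k, best_t = None, -np.inf
    n = len(x)
    for k in range(2, n - 1):
        a, b = x[:k], x[k:]
        pooled = np.sqrt(
            ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
            / (n - 2)
        )
        t = abs(a.mean() - b.mean()) / (pooled * np.sqrt(1 / len(a) + 1 / len(b)))
        if t > best_t:
            best_k, best_t = k, t
    return best_k


class TestLogRatios:
    def test_equal_depths_all_zero(self):
        targets = make_targets(50)
        kept, lr = cnv.compute_log_ratios(targets)
        assert len(kept) == 50
        assert np.allclose(lr, 0.0)

    def test_doubled_target_stands_out(self):
        targets = make_targets(50)
        targets[10] = TargetCoverage(
            interval=targets[10].interval, gene=targets[10].gene,
            tumor_depth=1000.0, normal_depth=500.0,
        )
        _, lr = cnv.compute_log_ratios(targets)
        assert lr[10] == pytest.approx(1.0, abs=0.05)
        assert np.abs(np.delete(lr, 10)).max() < 0.05

    def test_zero_comparator_target_dropped(self):
        targets = make_targets(10)
        targets[3] = TargetCoverage(
            interval=targets[3].interval, gene="G", tumor_depth=100.0,
            normal_depth=0.0,
        )
        kept, lr = cnv.compute_log_ratios(targets)
        assert len(kept) == 9

    def test_gc_correction_flattens_monotone_bias(self):
        rng = np.random.default_rng(0)
        targets = []
        for i in range(200):
            gc = 0.3 + 0.4 * i / 199
            bias = 2.0 ** (1.5 * (gc - 0.5))  # strong monotone GC trend
            targets.append(
                TargetCoverage(
                    interval=GenomicInterval("1", 1000 * i, 1000 * i + 200),
                    gene=f"G{i // 4}",
                    tumor_depth=500.0 * bias * rng.lognormal(0, 0.02),
                    normal_depth=500.0,
                    gc_fraction=gc,
                )
            )
        kept, lr = cnv.compute_log_ratios(targets, gc_correct=True)
        gcs = np.asarray([t.gc_fraction for t in kept])
        deciles = np.clip((gcs * 10).astype(int), 0, 9)
        for d in np.unique(deciles):
            assert abs(np.median(lr[deciles == d])) <= 0.05


class TestCbs:
    def test_constant_vector_single_segment(self):
        targets = make_targets(100)
        segs = cnv.cbs_segment(targets, np.zeros(100), n_perm=500, seed=0)
        assert len(segs) == 1
        assert segs[0].n_targets == 100

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_step_boundary_within_one_of_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.05, 100)
        targets = make_targets(100)
        segs = cnv.cbs_segment(targets, x, n_perm=2000, seed=seed + 1)
        assert len(segs) == 2
        boundary = segs[0].n_targets
        oracle = single_changepoint_oracle(x)
        assert abs(boundary - oracle) <= 1
        assert abs(boundary - 50) <= 1

    def test_pure_noise_rarely_splits(self):
        splits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(0, 0.3, 60)
            segs = cnv.cbs_segment(
                make_targets(60), x, alpha=0.01, n_perm=2000, seed=seed
            )
            splits += len(segs) > 1
        assert splits <= 0.05 * n_seeds + 1

    def test_shift_equivariance_of_boundaries(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([np.zeros(40), 0.8 * np.ones(30), np.zeros(30)])
        x = x + rng.normal(0, 0.05, 100)
        targets = make_targets(100)
        a = cnv.cbs_segment(targets, x, n_perm=1000, seed=9)
        b = cnv.cbs_segment(targets, x + 3.7, n_perm=1000, seed=9)
        assert [s.n_targets for s in a] == [s.n_targets for s in b]

    def test_chromosomes_segmented_independently(self):
        targets = make_targets(30) + make_targets(30, chrom="2")
        x = np.concatenate([np.zeros(30), np.ones(30)])
        segs = cnv.cbs_segment(targets, x, n_perm=500, seed=0)
        assert len(segs) == 2
        assert {s.interval.chrom for s in segs} == {"1", "2"}


class TestPurityPloidy:
    def test_noiseless_diploid_prefers_diploid_model(self):
        segs = [
            cnv.CopyNumberSegment(
                interval=GenomicInterval("1", 0, 10_000), n_targets=100,
                log2_ratio=0.0, mean_baf_deviation=0.0,
            )
        ]
        fit = cnv.estimate_purity_ploidy(segs)
        assert fit.ploidy == pytest.approx(2.0)
        assert fit.goodness_of_fit == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("purity", [1.0, 0.6, 0.3])
    def test_parameter_recovery_from_simulation(self, purity):
        hits = 0
        n_seeds = 4
        for seed in range(n_seeds):
            fit, cns = _recovery_run(purity, seed * 13 + 1)
            ok = abs(fit.purity - purity) <= 0.05 and cns == [1, 2, 4, 6]
            hits += ok
        assert hits == n_seeds

    def test_amplification_survives_at_purity_lod(self):
        # at the 30%-purity LOD a CN=6 amplification must stay CN > 2
        for seed in (11, 22):
            _, cns = _recovery_run(0.3, seed)
            assert max(cns) > 2

    def test_empty_grid_rejected(self):
        segs = [
            cnv.CopyNumberSegment(
                interval=GenomicInterval("1", 0, 1000), n_targets=1, log2_ratio=0.0
            )
        ]
        with pytest.raises(ParameterError):
            cnv.estimate_purity_ploidy(segs, grid=[])


def _recovery_run(purity, seed):
    """Simulated specimen: arm-scale CN-1 loss, focal CN-4 and CN-6 amps."""
    intervals, genes = [], []
    for g in range(30):
        for t in range(4):
            s = 10_000 * (g * 4 + t)
            intervals.append(GenomicInterval("1", s, s + 200))
            genes.append(f"GENE{g}")
    events = [(f"GENE{g}", 1) for g in range(6)]
    events += [("GENE10", 4), ("GENE20", 6)]
    sim = syn.simulate_coverage_profile(
        intervals, events, purity=purity, noise_sd=0.03, seed=seed,
        genes=genes, depth_mean=500.0,
    )
    kept, lr = cnv.compute_log_ratios(list(sim.targets))
    segs = cnv.cbs_segment(kept, lr, n_perm=1000, seed=seed + 1)
    fit = cnv.estimate_purity_ploidy(segs, list(sim.het_snvs))
    segs = cnv.assign_integer_cn(segs, fit)
    return fit, sorted(set(s.integer_cn for s in segs))


class TestIntegerAssignment:
    def _seg(self, ratio):
        return cnv.CopyNumberSegment(
            interval=GenomicInterval("1", 0, 1000), n_targets=10,
            log2_ratio=float(np.log2(ratio)),
        )

    @pytest.mark.parametrize(
        "purity,ratio,expected_cn",
        [(1.0, 2.0, 4), (0.5, 2.0, 6), (0.5, 1.0, 2)],
    )
    def test_mixture_inversion(self, purity, ratio, expected_cn):
        fit = cnv.PurityPloidyFit(
            purity=purity, ploidy=2.0, goodness_of_fit=0.0, penalty=0.0
        )
        (seg,) = cnv.assign_integer_cn([self._seg(ratio)], fit)
        assert seg.integer_cn == expected_cn

    def test_tie_takes_smaller_cn(self):
        # at purity 1.0 a ratio of 1.25 sits exactly between CN 2 and CN 3
        fit = cnv.PurityPloidyFit(
            purity=1.0, ploidy=2.0, goodness_of_fit=0.0, penalty=0.0
        )
        (seg,) = cnv.assign_integer_cn([self._seg(1.25)], fit)
        assert seg.integer_cn == 2


class TestEventCalls:
    def test_amplification_boundary_inclusive(self, config):
        assert cnv.call_focal_amplification(2.6, config)
        assert cnv.call_focal_amplification(2.5, config)
        assert not cnv.call_focal_amplification(1.0, config)

    def _segments(self, cn_by_range):
        return [
            cnv.CopyNumberSegment(
                interval=GenomicInterval(chrom, start, end), n_targets=10,
                log2_ratio=0.0, integer_cn=cn,
            )
            for chrom, start, end, cn in cn_by_range
        ]

    ARMS = [
        ("1p", GenomicInterval("1", 0, 120_000_000)),
        ("19q", GenomicInterval("19", 30_000_000, 59_000_000)),
    ]

    def test_1p19q_codeletion(self):
        segs = self._segments(
            [("1", 0, 100_000_000, 1), ("19", 31_000_000, 58_000_000, 1)]
        )
        calls = cnv.call_arm_events(segs, self.ARMS)
        assert calls == {"1p": "loss", "19q": "loss"}

    def test_diploid_genome_all_neutral(self):
        segs = self._segments(
            [("1", 0, 100_000_000, 2), ("19", 31_000_000, 58_000_000, 2)]
        )
        assert set(cnv.call_arm_events(segs, self.ARMS).values()) == {"neutral"}

    def test_half_arm_loss_below_80pct_rule(self):
        segs = self._segments(
            [("1", 0, 50_000_000, 1), ("1", 50_000_000, 100_000_000, 2)]
        )
        calls = cnv.call_arm_events(segs, self.ARMS[:1])
        assert calls == {"1p": "neutral"}

    def test_uncovered_arm_absent(self):
        segs = self._segments([("1", 0, 100_000_000, 2)])
        calls = cnv.call_arm_events(segs, self.ARMS)
        assert "19q" not in calls


class TestLinearityLadder:
    def test_noiseless_dilution_ladder_r2(self):
        """Gene-level fitted ratios are linear in true copy ratio (r^2 > 0.99)."""
        true_ratios, fitted = [], []
        intervals, genes = [], []
        for g in range(20):
            for t in range(4):
                s = 10_000 * (g * 4 + t)
                intervals.append(GenomicInterval("1", s, s + 200))
                genes.append(f"GENE{g}")
        for purity in np.linspace(0.05, 0.5, 5):
            sim = syn.simulate_coverage_profile(
                intervals, [("GENE7", 6)], purity=float(purity), noise_sd=0.0,
                seed=1, genes=genes,
            )
            kept, lr = cnv.compute_log_ratios(list(sim.targets))
            gene_ratio = cnv.gene_level_ratios(kept, lr)["GENE7"]
            fitted.append(gene_ratio)
            true_ratios.append((purity * 6 + 2 * (1 - purity)) / 2.0)
        r = np.corrcoef(true_ratios, fitted)[0, 1]
        assert r * r > 0.99
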