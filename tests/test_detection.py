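import math

import numpy as np
import pytest

from lunghist.detection import (
    DetectedCase,
    DetectionParams,
    cycle_detection,
    make_cohort_draws,
    mode_hazards,
    simulate_tumors,
    stage_label,
    stage_probs_given_size,
)
from lunghist.progression import ProgressionParams, TumorCourse


class TestModeHazards:
    def test_no_mets(self, dp):
        h_p, h_n, h_d = mode_hazards(2.0, 0, 0, dp)
        assert h_p == pytest.approx(dp.eta * 2.0 + dp.w0)
        assert h_n == 0.0 and h_d == 0.0

    def test_distant_to_nodal_ratio(self, dp):
        """With both metastases present the distant/nodal hazard ratio is
        w2/w1 ~ 46.7 regardless of size (for sizes where eta*s is small)."""
        for s in (0.5, 10.0, 100.0):
            _, h_n, h_d = mode_hazards(s, 1, 1, dp)
            assert h_d / h_n == pytest.approx(dp.w2 / dp.w1)
            assert h_d / h_n == pytest.approx(46.67, abs=0.01)

    def test_met_offsets_dominate_primary(self, dp):
        # w1, w2 >> w0: metastatic disease is detected almost immediately
        h_p, h_n, h_d = mode_hazards(1.0, 1, 1, dp)
        assert h_n > 1e3 * h_p and h_d > 1e4 * h_p

    def test_stage_hazard_family(self, dp):
        s = 3.0
        z = {}
        for N in (0, 1):
            for M in (0, 1):
                z[(N, M)] = sum(mode_hazards(s, N, M, dp))
        assert z[(0, 0)] == pytest.approx(dp.eta * s + dp.w0)
        assert z[(1, 0)] == pytest.approx(z[(0, 0)] + dp.w1)
        assert z[(0, 1)] == pytest.approx(z[(0, 0)] + dp.w2)
        assert z[(1, 1)] == pytest.approx(z[(0, 0)] + dp.w1 + dp.w2)

    def test_nonpositive_size_rejected(self, dp):
        with pytest.raises(ValueError):
            mode_hazards(0.0, 0, 0, dp)


class TestStageLabel:
    @pytest.mark.parametrize(
        "N,M,label", [(0, 0, "N0M0"), (1, 0, "NxM0"), (0, 1, "M1"), (1, 1, "M1")]
    )
    def test_labels(self, N, M, label):
        assert stage_label(N, M) == label

    def test_detected_case_consistency(self):
        with pytest.raises(ValueError):
            DetectedCase(0, 65.0, "nodal", 1.0, 1.24, N=0, M=0, stage="N0M0")
        with pytest.raises(ValueError):
            DetectedCase(0, 65.0, "primary", 1.0, 1.24, N=0, M=1, stage="N0M0")


class TestCycleDetection:
    def test_zero_hazards_never_detect(self, rng):
        dp = DetectionParams(eta=0.0, w0=0.0, w1=0.0, w2=0.0)
        course = TumorCourse(0, 60.0, 4.0, t_nodal=3.0, t_distant=4.0)
        assert cycle_detection(course, dp, rng, censor_age=110.0) is None

    def test_huge_w0_detects_first_cycle(self, rng):
        dp = DetectionParams(w0=1e9)
        course = TumorCourse(0, 60.0, 4.0, t_nodal=5.0, t_distant=6.0)
        case = cycle_detection(course, dp, rng, censor_age=110.0)
        assert case is not None
        assert case.detection_age == pytest.approx(61.0)
        assert case.mode == "primary" and case.stage == "N0M0"

    def test_censoring_by_death(self, rng):
        course = TumorCourse(0, 60.0, 0.001, t_nodal=1e6, t_distant=1e6)
        assert cycle_detection(course, DetectionParams(), rng, censor_age=60.5) is None

    def test_geometric_cycle_distribution(self, dp):
        """Constant-size toy (lambda ~ 0, mets always present): the
        detection cycle is geometric with p = 1 - exp(-z11 * cycle)."""
        dp_toy = DetectionParams(eta=0.0, w0=0.05, w1=0.1, w2=0.2)
        rng = np.random.default_rng(4)
        course = TumorCourse(0, 50.0, 1e-9, t_nodal=1e-6, t_distant=1e-6)
        z = 0.05 + 0.1 + 0.2
        p = 1.0 - math.exp(-z)
        n = 30_000
        cycles = []
        for _ in range(n):
            case = cycle_detection(course, dp_toy, rng, censor_age=1e9)
            cycles.append(round(case.detection_age - course.onset_age))
        cycles = np.asarray(cycles)
        for k in (1, 2, 3, 5):
            expected = (1 - p) ** (k - 1) * p
            emp = float((cycles == k).mean())
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(emp - expected) < 3 * se + 1e-4

    def test_small_cycle_converges_to_continuous_time(self):
        """As cycle_years -> 0 the detection-time law approaches the
        continuous inhomogeneous-exponential solution for a toy with
        analytic cumulative hazard H(t) = w0 t (fixed size, no mets)."""
        w0 = 0.3
        rng = np.random.default_rng(12)
        course = TumorCourse(0, 50.0, 1e-9, t_nodal=1e9, t_distant=1e9)
        dp_fine = DetectionParams(eta=0.0, w0=w0, w1=0.0, w2=0.0, cycle_years=1 / 64)
        n = 4000
        times = np.array(
            [
                cycle_detection(course, dp_fine, rng, censor_age=1e9).detection_age
                - 50.0
                for _ in range(n)
            ]
        )
        for t in (1.0, 3.0, 6.0):
            exact = 1.0 - math.exp(-w0 * t)
            emp = float((times <= t).mean())
            se = math.sqrt(exact * (1 - exact) / n)
            assert abs(emp - exact) < 3 * se + 1.5 * w0 / 64


class TestBatchSimulator:
    def test_matches_scalar_path_statistically(self, pp, dp):
        """Batch pipeline and per-tumor loop agree on detection fraction
        and stage mix."""
        n = 4000
        rng1 = np.random.default_rng(31)
        onset = np.full(n, 60.0)
        censor = np.full(n, 85.0)
        batch = simulate_tumors(pp, dp, rng1, onset, censor)
        det_b = batch[batch["detected"]]

        rng2 = np.random.default_rng(32)
        from lunghist.progression import sample_growth_rate, sample_met_times

        lam = sample_growth_rate(pp, rng2, n)
        t_n, t_m = sample_met_times(lam, pp, rng2)
        scalar_cases = []
        for i in range(n):
            c = TumorCourse(i, 60.0, lam[i], t_nodal=t_n[i], t_distant=t_m[i])
            case = cycle_detection(c, dp, rng2, censor_age=85.0)
            if case is not None:
                scalar_cases.append(case)
        frac_b = len(det_b) / n
        frac_s = len(scalar_cases) / n
        se = math.sqrt(frac_b * (1 - frac_b) / n)
        assert abs(frac_b - frac_s) < 4 * se
        m1_b = (det_b["stage"] == "M1").mean()
        m1_s = np.mean([c.stage == "M1" for c in scalar_cases])
        assert abs(m1_b - m1_s) < 4 * math.sqrt(m1_b * (1 - m1_b) / len(det_b))

    def test_mode_frequencies_match_hazard_proportions(self, pp):
        """Competing-risks contract: conditional on (N, M) at detection,
        mode frequencies are proportional to the mode hazards."""
        dp = DetectionParams(eta=1e-3, w0=0.3, w1=0.6, w2=1.2)
        rng = np.random.default_rng(8)
        n = 60_000
        onset = np.full(n, 55.0)
        censor = np.full(n, 100.0)
        df = simulate_tumors(pp, dp, rng, onset, censor)
        det = df[df["detected"] & (df["N"] == 1) & (df["M"] == 1)]
        assert len(det) > 5000
        # size-dependent h_p varies per case; use expected proportions case-wise
        h_p = dp.eta * det["volume_cm3"].to_numpy() + dp.w0
        probs = np.stack([h_p, np.full_like(h_p, dp.w1), np.full_like(h_p, dp.w2)])
        probs /= probs.sum(axis=0)
        for j, mode in enumerate(("primary", "nodal", "distant")):
            expected = probs[j].mean()
            emp = (det["mode"] == mode).mean()
            se = math.sqrt(expected * (1 - expected) / len(det))
            assert abs(emp - expected) < 3.5 * se + 1e-3

    def test_stage_probabilities_sum_to_one_by_bin(self, pp, dp):
        rng = np.random.default_rng(21)
        n = 50_000
        onset = rng.uniform(40.0, 80.0, n)
        censor = onset + 60.0
        df = simulate_tumors(pp, dp, rng, onset, censor)
        det = df[df["detected"]]
        bins = np.minimum(np.floor(det["diameter_cm"]), 19)
        for b, grp in det.groupby(bins):
            if len(grp) < 100:
                continue
            shares = [
                (grp["N"] == 0).pipe(lambda s: ((grp["N"] == 0) & (grp["M"] == 0)).mean()),
                ((grp["N"] == 1) & (grp["M"] == 0)).mean(),
                ((grp["N"] == 0) & (grp["M"] == 1)).mean(),
                ((grp["N"] == 1) & (grp["M"] == 1)).mean(),
            ]
            assert sum(shares) == pytest.approx(1.0, abs=1e-9)

    def test_no_detection_after_censor(self, pp, dp, rng):
        n = 5000
        onset = np.full(n, 70.0)
        censor = np.full(n, 76.0)
        df = simulate_tumors(pp, dp, rng, onset, censor)
        det = df[df["detected"]]
        assert np.all(det["detection_age"] <= 76.0)

    def test_crn_determinism(self, pp, dp):
        n = 2000
        rng = np.random.default_rng(77)
        onset = np.full(n, 60.0)
        censor = np.full(n, 100.0)
        draws = make_cohort_draws(n, rng)
        a = simulate_tumors(pp, dp, None, onset, censor, draws=draws)
        b = simulate_tumors(pp, dp, None, onset, censor, draws=draws)
        assert a.equals(b)


class TestStageProbsGivenSize:
    def test_no_mets_when_rates_vanish(self, dp):
        pp0 = ProgressionParams(mu_n=1e-18, mu_m=1e-18)
        p_n, p_m, cnt = stage_probs_given_size(
            2.5, pp0, dp, n=20_000, rng=np.random.default_rng(5)
        )
        assert p_n == 0.0 and p_m == 0.0 and cnt >= 100

    def test_distant_probability_increases_with_size(self, pp, dp):
        rng = np.random.default_rng(6)
        p_small = stage_probs_given_size(2.5, pp, dp, n=60_000, rng=rng)[1]
        p_large = stage_probs_given_size(6.5, pp, dp, n=60_000, rng=rng)[1]
        assert p_large > p_small

    def test_insufficient_sample_signalled(self, pp, dp):
        with pytest.raises(RuntimeError, match="detected cases"):
            stage_probs_given_size(
                19.5, pp, dp, n=2000, rng=np.random.default_rng(7), min_count=1000
            )


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(eta=-1.0)
    with pytest.raises(ValueError):
        DetectionParams(cycle_years=0.0)
    with pytest.raises(ValueError):
        DetectionParams(size_unit="inches")
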