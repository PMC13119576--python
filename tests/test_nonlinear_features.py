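"""Temporal-structure estimators against naive reference implementations
and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copsway.core import CoPTrial
from copsway.nonlinear_features import (
    CalibrationError,
    EmbeddingSpec,
    delay_embedding,
    dfa,
    katz_fd,
    mse,
    rqa,
    rqa_auto,
    sample_entropy,
    sda,
    select_delay_ami,
    select_dim_fnn,
    sway_density,
)
from copsway.synthetic_data import SynthSignalParams, gen_cop_trial, gen_ou_walk


def _trial(ap, ml, fs=100.0):
    return CoPTrial("T", "EO_firm", 1, fs, np.asarray(ap, float), np.asarray(ml, float))


# ---------------------------------------------------------------------------
# Naive reference implementations (kept deliberately independent and slow)
# ---------------------------------------------------------------------------

def naive_sampen(x, m, r):
    n = len(x) - m
    a = b = 0
    for i, j in itertools.combinations(range(n), 2):
        if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
            b += 1
            if abs(x[i + m] - x[j + m]) <= r:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def naive_rqa(x, delay, dim, eps, theiler, lmin):
    n = len(x) - (dim - 1) * delay
    emb = [[x[i + k * delay] for k in range(dim)] for i in range(n)]
    rec = [
        [
            abs(i - j) > theiler
            and math.dist(emb[i], emb[j]) <= eps
            for j in range(n)
        ]
        for i in range(n)
    ]

    def runs(seq):
        out, cur = [], 0
        for v in seq:
            if v:
                cur += 1
            elif cur:
                out.append(cur)
                cur = 0
        if cur:
            out.append(cur)
        return out

    diag_pts = diag_line_pts = 0
    for off in range(theiler + 1, n):
        seq = [rec[i][i + off] for i in range(n - off)]
        diag_pts += sum(seq)
        diag_line_pts += sum(r for r in runs(seq) if r >= lmin)
    vert_pts = vert_line_pts = 0
    for j in range(n):
        seq = [rec[i][j] for i in range(n)]
        vert_pts += sum(seq)
        vert_line_pts += sum(r for r in runs(seq) if r >= lmin)
    det = diag_line_pts / diag_pts if diag_pts else float("nan")
    lam = vert_line_pts / vert_pts if vert_pts else float("nan")
    rr_pts = sum(sum(row) for row in rec)
    n_valid = n * n - (2 * theiler + 1) * n + theiler * (theiler + 1)
    return det, lam, rr_pts / n_valid


def naive_katz(ap, ml):
    n = len(ap) - 1
    L = sum(math.hypot(ap[i + 1] - ap[i], ml[i + 1] - ml[i]) for i in range(n))
    d = max(math.hypot(ap[i] - ap[0], ml[i] - ml[0]) for i in range(len(ap)))
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


# ---------------------------------------------------------------------------
# Sway density
# ---------------------------------------------------------------------------

class TestSwayDensity:
    def test_constant_trajectory_undefined(self):
        res = sway_density(_trial(np.zeros(1000), np.zeros(1000)))
        assert not res.defined
        assert np.isnan(res.mt3) and np.isnan(res.md3)

    def test_two_cluster_dwell_distances(self):
        # alternate 1.5-s dwells at (0,0) and (2,0) with 0.5-s transitions
        segs, cur = [], 0.0
        for b in range(30):
            tgt = 2.0 if b % 2 else 0.0
            segs.append(np.linspace(cur, tgt, 50, endpoint=False))
            segs.append(np.full(150, tgt))
            cur = tgt
        x = np.concatenate(segs)
        res = sway_density(_trial(x, np.zeros_like(x)))
        assert res.md3 == pytest.approx(2.0, abs=0.1)
        assert res.mt3 == pytest.approx(2.0, abs=0.3)

    def test_fast_trajectory_has_small_peaks(self):
        # steady 1 cm/s drift: only ~2*radius/speed seconds fall in any ball
        x = np.arange(6000) / 100.0
        res = sway_density(_trial(x, np.zeros_like(x)))
        assert res.mp3 < 1.5  # far below the 60-s ceiling


class TestKatzFD:
    def test_straight_line_is_exactly_one(self):
        x = np.linspace(0, 5, 100)
        assert katz_fd(_trial(x, 2 * x)) == 1.0

    def test_random_walk_matches_naive_formula(self, rng):
        ap = rng.standard_normal(500).cumsum()
        ml = rng.standard_normal(500).cumsum()
        assert katz_fd(_trial(ap, ml)) == pytest.approx(naive_katz(ap, ml), rel=1e-12)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_fd_at_least_one(self, seed):
        r = np.random.default_rng(seed)
        assert katz_fd(_trial(r.standard_normal(200), r.standard_normal(200))) >= 1.0

    def test_constant_trajectory_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert katz_fd(_trial(np.zeros(50), np.zeros(50))) == 1.0


class TestDFA:
    def test_white_noise_exponent(self):
        est = np.mean(
            [dfa(np.random.default_rng(s).standard_normal(6000))[0] for s in range(5)]
        )
        assert est == pytest.approx(0.5, abs=0.05)

    def test_brownian_exponent(self):
        est = np.mean(
            [dfa(np.cumsum(np.random.default_rng(s).standard_normal(6000)))[0] for s in range(5)]
        )
        assert est == pytest.approx(1.5, abs=0.08)

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(3000)
        assert dfa(x)[0] == pytest.approx(dfa(-x)[0], abs=1e-12)

    def test_too_few_box_sizes_rejected(self):
        with pytest.raises(ValueError, match="box sizes"):
            dfa(np.random.default_rng(0).standard_normal(1000), box_sizes=[10, 20])


class TestSDA:
    def test_ou_walk_against_closed_form_fit(self):
        # oracle: fit the same windows on the analytic OU MSD curve
        sigma, tau, fs = 0.5, 1.0, 100.0
        lags = np.arange(1, 1001) / fs
        msd_true = 4 * sigma**2 * (1 - np.exp(-lags / tau))

        def fit(window):
            m = (lags >= window[0]) & (lags <= window[1])
            return np.polyfit(lags[m], msd_true[m], 1)[0] / 4

        ds_true, dl_true = fit((0.1, 0.8)), fit((2.0, 10.0))
        ds, dl, crit = [], [], []
        for s in range(10):
            w = gen_ou_walk(sigma, tau, 6000, fs, s)
            r = sda(_trial(w[:, 0], w[:, 1]))
            ds.append(r.ds)
            dl.append(r.dl)
            crit.append(r.crit_t)
        assert np.mean(ds) == pytest.approx(ds_true, rel=0.10)
        assert abs(np.mean(dl)) < 0.1 * ds_true  # long-term plateau
        assert 0.2 * tau < np.median(crit) < 5 * tau

    def test_constant_trajectory_flagged(self):
        r = sda(_trial(np.zeros(2000), np.zeros(2000)))
        assert r.flagged
        assert "MSD" in r.diagnostics["reason"]


class TestSampleEntropy:
    @pytest.mark.parametrize("r_factor", [0.15, 0.2, 0.3])
    def test_exact_match_with_naive_oracle(self, rng, r_factor):
        x = rng.standard_normal(300)
        r = r_factor * x.std()
        assert sample_entropy(x, 2, r) == pytest.approx(naive_sampen(x, 2, r), abs=1e-12)

    def test_periodic_sawtooth_is_zero(self):
        x = np.tile(np.arange(10.0), 40)
        assert sample_entropy(x, 2, 0.2 * x.std()) == 0.0

    def test_white_noise_entropy_decreases_with_scale(self, rng):
        x = rng.standard_normal(6000)
        ent = mse(x, scales=(1, 10, 40))
        assert ent[1] > ent[10] > ent[40]

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(500)
        r = 0.2 * x.std()
        assert sample_entropy(x, 2, r) == sample_entropy(-x, 2, r)

    def test_short_series_for_scale_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            mse(np.random.default_rng(0).standard_normal(500), scales=(1, 10, 40))


class TestEmbeddingSelection:
    def test_sinusoid_delay_near_quarter_period(self):
        t = np.arange(6000) / 100.0
        tau = select_delay_ami(np.sin(2 * np.pi * 0.5 * t))  # P = 200 samples
        assert 30 <= tau <= 70

    def test_white_noise_delay_is_one(self, rng):
        assert select_delay_ami(rng.standard_normal(6000)) == 1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            select_delay_ami(np.ones(1000))

    def test_delay_deterministic(self, cop_trial):
        a = select_delay_ami(cop_trial.cop_ap)
        b = select_delay_ami(cop_trial.cop_ap)
        assert a == b

    def test_sinusoid_embeds_in_two_dimensions(self):
        t = np.arange(6000) / 100.0
        assert select_dim_fnn(np.sin(2 * np.pi * 0.5 * t), 50) == 2

    def test_white_noise_saturates_max_dim(self, rng):
        assert select_dim_fnn(rng.standard_normal(3000), 1, max_dim=8) == 8

    def test_fnn_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            select_dim_fnn(np.random.default_rng(0).standard_normal(100), 20, max_dim=10)


class TestRQA:
    def test_toy_series_matches_naive_line_counting(self, rng):
        x = rng.standard_normal(80).cumsum()
        spec = EmbeddingSpec(delay=3, dim=2, threshold=1.5)
        res = rqa(x, spec, lmin=2, theiler=3, min_points=10)
        det, lam, rr = naive_rqa(x, 3, 2, 1.5, 3, 2)
        assert res.det == pytest.approx(det, abs=1e-12)
        assert res.lam == pytest.approx(lam, abs=1e-12)
        assert res.achieved_rr == pytest.approx(rr, abs=1e-12)

    def test_calibrated_toy_series_matches_naive_at_same_threshold(self, rng):
        x = rng.standard_normal(100).cumsum()
        res = rqa(x, EmbeddingSpec(delay=2, dim=2), theiler=2, min_points=10)
        assert 0.045 <= res.achieved_rr <= 0.055
        det, lam, rr = naive_rqa(x, 2, 2, res.spec.threshold, 2, 2)
        assert res.det == pytest.approx(det, abs=1e-12)
        assert res.lam == pytest.approx(lam, abs=1e-12)

    def test_sinusoid_more_deterministic_than_noise(self, rng):
        t = np.arange(3000) / 100.0
        sine = np.sin(2 * np.pi * 0.5 * t)
        noise = rng.standard_normal(3000)
        det_sine = rqa(sine, EmbeddingSpec(delay=50, dim=2), theiler=50).det
        det_noise = rqa(noise, EmbeddingSpec(delay=1, dim=2), theiler=1).det
        assert det_noise < 0.5 * det_sine

    def test_det_lam_bounded(self, cop_trial):
        res = rqa_auto(cop_trial.cop_ml)
        assert 0.0 <= res.det <= 1.0
        assert 0.0 <= res.lam <= 1.0
        assert 0.045 <= res.achieved_rr <= 0.055

    def test_offset_invariance(self, rng):
        x = rng.standard_normal(600).cumsum()
        a = rqa(x, EmbeddingSpec(delay=2, dim=3), min_points=10)
        b = rqa(x + 100.0, EmbeddingSpec(delay=2, dim=3), min_points=10)
        assert a.det == pytest.approx(b.det, abs=5e-3)
        assert a.lam == pytest.approx(b.lam, abs=5e-3)

    def test_constant_series_fails_calibration(self):
        with pytest.raises((CalibrationError, ValueError)):
            rqa(np.zeros(400), EmbeddingSpec(delay=1, dim=2), min_points=10)

    def test_embedding_shape(self):
        emb = delay_embedding(np.arange(10.0), delay=2, dim=3)
        assert emb.shape == (6, 3)
        np.testing.assert_array_equal(emb[0], [0, 2, 4])
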