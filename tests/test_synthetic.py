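"""Statistical properties of the synthetic-embryo generator."""
import math

import numpy as np
import pytest
from scipy import stats

from burstkin import (
    GradientConfig,
    make_spot_fixture,
    render_trace,
    simulate_embryo,
    simulate_promoter_path,
    simulate_smfish_counts,
)
from burstkin.synthetic import ConfigurationError
from burstkin.types import (
    BackgroundModel,
    EmissionModel,
    InvalidParameterError,
    KineticParams,
    PromoterPath,
)

from conftest import DT


class TestPromoterPath:
    def test_absorbing_off_limit(self):
        """With a vanishing activation rate and an OFF start, the path stays off."""
        params = KineticParams(k_on=1e-12, k_off=1.0, k_ini=1.0)
        path = simulate_promoter_path(params, 200, DT, seed=0, initial_state=0)
        assert path.states.sum() == 0

    def test_switch_frequency_matches_closed_form(self):
        """Empirical per-frame switch frequency matches p = 1 - exp(-k dt)."""
        params = KineticParams(k_on=1.0, k_off=1.0, k_ini=1.0)
        p_expected = 1.0 - math.exp(-DT)
        assert p_expected == pytest.approx(0.2835, abs=1e-4)
        path = simulate_promoter_path(params, 100_000, DT, seed=42)
        s = path.states
        for from_state, to_state in ((0, 1), (1, 0)):
            at = np.flatnonzero(s[:-1] == from_state)
            p_hat = float((s[at + 1] == to_state).mean())
            se = math.sqrt(p_expected * (1 - p_expected) / at.size)
            assert abs(p_hat - p_expected) < 3 * se

    def test_stationary_occupancy(self):
        """Long-run ON fraction: exact discrete law, approaching k_on/(k_on+k_off) as dt -> 0.

        With the exponential hold conversion the frame chain's stationary
        occupancy is p01/(p01+p10); it equals the continuous-time value
        k_on/(k_on+k_off) in the dt -> 0 limit with an O(dt) gap.
        """
        params = KineticParams(k_on=0.5, k_off=1.0, k_ini=1.0)
        for dt, n in ((DT, 200_000), (0.02, 300_000)):
            p01, p10 = params.switch_probabilities(dt)
            pi_on = p01 / (p01 + p10)
            path = simulate_promoter_path(params, n, dt, seed=7)
            # frames are autocorrelated; inflate the SE by the chain's
            # integrated autocorrelation time (eigenvalue 1 - p01 - p10)
            lam = 1.0 - p01 - p10
            n_eff = n * (1 - lam) / (1 + lam)
            se = math.sqrt(pi_on * (1 - pi_on) / n_eff)
            assert abs(path.fraction_on - pi_on) < 3 * se
        # the discrete stationary law converges to the rate ratio
        p01, p10 = params.switch_probabilities(0.02)
        assert p01 / (p01 + p10) == pytest.approx(1 / 3, abs=0.002)

    def test_dwell_times_are_geometric(self):
        """ON/OFF run lengths pass a chi-square geometric GOF at alpha=0.01."""
        from burstkin.mhmm import dwell_time_check

        params = KineticParams(k_on=0.5, k_off=1.0, k_ini=1.0)
        paths = [simulate_promoter_path(params, 2000, DT, seed=s) for s in range(60)]
        rep = dwell_time_check(paths)
        assert rep.on_dwells.size > 10_000 and rep.off_dwells.size > 10_000
        assert rep.p_value_on > 0.01
        assert rep.p_value_off > 0.01

    def test_deterministic_under_seed(self):
        params = KineticParams(0.5, 1.0, 1.0)
        a = simulate_promoter_path(params, 500, DT, seed=3)
        b = simulate_promoter_path(params, 500, DT, seed=3)
        assert np.array_equal(a.states, b.states)

    def test_invalid_inputs_raise(self):
        params = KineticParams(0.5, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            simulate_promoter_path(params, 0, DT, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_promoter_path(params, 10, -1.0, seed=0)
        with pytest.raises(InvalidParameterError):
            KineticParams(-0.5, 1.0, 1.0)


class TestRenderTrace:
    def test_all_off_renders_zero(self, emission_k6):
        path = PromoterPath(np.zeros(30, dtype=np.int8), DT)
        tr = render_trace(path, 20.0, emission_k6, noise_sd=0.0)
        assert np.all(tr.fluor == 0.0)

    def test_saturation_plateau(self):
        """All-ON path with unit weights plateaus at v*k_ini*dt*K after K frames."""
        em = EmissionModel(weights=np.ones(5), dt=DT, v=2.0)
        path = PromoterPath(np.ones(20, dtype=np.int8), DT)
        tr = render_trace(path, 10.0, em, noise_sd=0.0)
        plateau = 2.0 * 10.0 * DT * 5
        assert tr.fluor[5:] == pytest.approx(plateau)
        # ramp during the first K frames
        assert np.all(np.diff(tr.fluor[:5]) > 0)

    def test_single_pulse_is_the_weight_sequence(self, emission_k6):
        """A one-frame pulse reproduces v*k_ini*dt*w_i at lag i, 0 beyond K."""
        states = np.zeros(15, dtype=np.int8)
        states[2] = 1
        tr = render_trace(PromoterPath(states, DT), 20.0, emission_k6, noise_sd=0.0)
        amp = 20.0 * DT
        K = emission_k6.K
        for lag in range(K):
            assert tr.fluor[2 + lag] == pytest.approx(amp * emission_k6.weights[lag])
        assert np.all(tr.fluor[2 + K :] == 0.0)
        assert np.all(tr.fluor[:2] == 0.0)

    def test_missing_frames_flagged_and_noise_rejected(self, emission_k6):
        path = PromoterPath(np.ones(10, dtype=np.int8), DT)
        tr = render_trace(path, 5.0, emission_k6, missing_frames=(3, 7), seed=1)
        assert tr.missing[3] and tr.missing[7] and tr.missing.sum() == 2
        with pytest.raises(InvalidParameterError):
            render_trace(path, 5.0, emission_k6, noise_sd=-1.0)


class TestSimulateEmbryo:
    def test_band_means_decrease_outward(self, emission_k6):
        """Mean expression strictly decreases across k_on = 0.8/0.5/0.2 bands."""
        grad = GradientConfig(missing_frame_rate=0.0)
        base = KineticParams(0.8, 1.0, 20.0, noise_sd=1.0)
        traces, truth = simulate_embryo(
            grad, base, emission_k6, n_frames=150, background=None, seed=2,
            apply_onset_delay=False,
        )
        means = {}
        for tr in traces:
            band = truth.band[tr.nucleus_id]
            means.setdefault(band, []).append(tr.fluor.mean())
        band_means = [np.mean(means[b]) for b in sorted(means)]
        assert len(band_means) == 3
        assert band_means[0] > band_means[1] > band_means[2]

    def test_single_band_is_homogeneous(self, emission_k6):
        grad = GradientConfig(bands=((math.inf, 0.5),), n_rows=4, n_cols=2)
        base = KineticParams(0.5, 1.0, 20.0)
        _, truth = simulate_embryo(grad, base, emission_k6, n_frames=50, seed=0)
        assert len({p.k_on for p in truth.params.values()}) == 1

    def test_default_band_layout_is_15_30(self):
        """Default edges at 15 and 30 μm mirror the high/medium/low regions."""
        grad = GradientConfig()
        assert grad.k_on_at(12.0) == 0.8
        assert grad.k_on_at(-12.0) == 0.8
        assert grad.k_on_at(20.0) == 0.5
        assert grad.k_on_at(31.0) == 0.2

    def test_onset_delay_holds_promoter_off(self, emission_k6):
        grad = GradientConfig(onset_base_min=10.0, onset_slope_min_per_um=0.0,
                              missing_frame_rate=0.0)
        base = KineticParams(0.8, 1.0, 20.0)
        _, truth = simulate_embryo(grad, base, emission_k6, n_frames=100, seed=1)
        onset_frame = int(math.ceil(10.0 / DT))
        for path in truth.paths.values():
            assert path.states[:onset_frame].sum() == 0

    def test_invalid_band_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GradientConfig(bands=((15.0, 0.5), (30.0, 0.8), (math.inf, 0.2)))
        with pytest.raises(ConfigurationError):
            GradientConfig(bands=((30.0, 0.8), (15.0, 0.5)))

    def test_reproducible_under_seed(self, emission_k6):
        grad = GradientConfig(n_rows=4, n_cols=2)
        base = KineticParams(0.8, 1.0, 20.0, noise_sd=1.0)
        a, _ = simulate_embryo(grad, base, emission_k6, n_frames=40, seed=9)
        b, _ = simulate_embryo(grad, base, emission_k6, n_frames=40, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.fluor, tb.fluor)
            assert np.array_equal(ta.missing, tb.missing)


class TestSmfishCounts:
    def test_pure_birth_is_poisson(self):
        """No decay, promoter effectively always ON: counts ~ Poisson(n_alleles*k_ini*t)."""
        params = KineticParams(k_on=500.0, k_off=1e-9, k_ini=5.0)
        df = simulate_smfish_counts(params, math.inf, t_fix=10.0, n_cells=4000,
                                    n_alleles=2, seed=0)
        mean_expected = 2 * 5.0 * 10.0
        m = df["count"].mean()
        se = math.sqrt(mean_expected / len(df))
        assert abs(m - mean_expected) < 3 * se
        # Poisson: variance ~= mean
        assert df["count"].var() == pytest.approx(mean_expected, rel=0.1)

    def test_steady_state_mean_fast_switching(self):
        """t_fix >> 1/delta, fast switching: mean ~= n_alleles*k_ini*occ/delta."""
        params = KineticParams(k_on=5.0, k_off=5.0, k_ini=20.0)
        half_life = 3.0
        delta = math.log(2) / half_life
        df = simulate_smfish_counts(params, half_life, t_fix=25.0, n_cells=3000,
                                    n_alleles=2, seed=1)
        expected = 2 * 20.0 * 0.5 / delta
        m = df["count"].mean()
        se = df["count"].std() / math.sqrt(len(df))
        assert abs(m - expected) < 3 * se

    def test_active_flag_frequency(self):
        """P(allele active at fixation) is the stationary occupancy."""
        params = KineticParams(k_on=0.5, k_off=1.0, k_ini=5.0)
        df = simulate_smfish_counts(params, 12.0, t_fix=30.0, n_cells=3000,
                                    n_alleles=2, seed=2)
        frac = df["n_active"].mean() / 2
        se = math.sqrt((1 / 3) * (2 / 3) / (2 * len(df)))
        assert abs(frac - 1 / 3) < 3 * se

    def test_invalid_inputs(self):
        params = KineticParams(0.5, 1.0, 5.0)
        with pytest.raises(InvalidParameterError):
            simulate_smfish_counts(params, 12.0, t_fix=-1.0, n_cells=5)
        with pytest.raises(InvalidParameterError):
            simulate_smfish_counts(params, 12.0, t_fix=10.0, n_cells=5, n_alleles=0)


class TestSpotFixture:
    def test_flat_midline_offsets_are_truth(self):
        nuc, _ = make_spot_fixture((0.0, 0.0, 50.0), n_nuclei=5, seed=0)
        assert np.allclose(nuc["y_um"] - 50.0, nuc["true_offset_um"])

    def test_noiseless_quadratic_recovered(self):
        from burstkin import fit_midline

        nuc, spots = make_spot_fixture(
            (0.01, 0.0, 50.0), n_nuclei=40, spots_per_cell=4,
            offset_sd_um=0.0, spot_scatter_um=0.0, seed=1,
        )
        m = fit_midline(spots)
        assert m.a == pytest.approx(0.01, abs=1e-6)
        assert m.b == pytest.approx(0.0, abs=1e-6)
        assert m.c == pytest.approx(50.0, abs=1e-6)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            make_spot_fixture((0, 0, 0), n_nuclei=5, axis_half_length_um=0.0)
        with pytest.raises(ConfigurationError):
            make_spot_fixture((0, 0, 0), n_nuclei=2)
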