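"""Unit and property tests of the neural-mass and hemodynamic forward model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pmfm import (
    Connectome,
    LinearCoefficients,
    ModelConstants,
    RegionalParameters,
    SimulationConfig,
    SpatialMap,
    balloon_windkessel,
    build_regional_parameters,
    integrate_mfm,
    n_free_parameters,
    simulate_bold,
    transfer_function,
)
from pmfm.dynamics import HemodynamicConstants, NeuralTrajectory, downsample_bold
from pmfm.exceptions import (
    DivergenceError,
    InfeasibleParametersError,
    InvalidInputError,
)

CONST = ModelConstants()


def drift(s, w, I, c=CONST):
    x = w * c.J * s + I
    return -s / c.tau_s + c.r_kin * (1 - s) * transfer_function(x, c)


class TestTransferFunction:
    @pytest.mark.parametrize(
        "x,expected,tol",
        [
            (108.0 / 270.0, 1.0 / 0.154, 1e-9),       # removable singularity -> 1/d
            (1.0, 162.00000000237, 1e-6),              # a*x-b = 162, denominator ~ 1
            (0.0, 6.460080925634537e-06, 1e-12),       # deep subthreshold
        ],
    )
    def test_reference_values(self, x, expected, tol):
        assert transfer_function(x) == pytest.approx(expected, abs=tol)

    def test_continuous_at_singularity(self):
        eps = 1e-7
        x0 = CONST.b / CONST.a
        assert transfer_function(x0 - eps) == pytest.approx(transfer_function(x0 + eps), rel=1e-4)

    def test_strictly_positive_and_increasing(self):
        x = np.linspace(-2, 3, 2001)
        h = transfer_function(x)
        assert np.all(h > 0)
        assert np.all(np.diff(h) > 0)

    def test_linear_asymptote(self):
        # exp(-d*u) sets the relative gap: ~1e-4 at u=60, <1e-6 once u >= 90
        for u, rel in [(60.0, 1e-4), (90.0, 1e-6), (200.0, 1e-9)]:
            x = (u + CONST.b) / CONST.a
            assert transfer_function(x) == pytest.approx(u, rel=rel)

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            transfer_function(np.nan)


class TestRegionalParameters:
    def test_constant_offsets(self):
        maps = (SpatialMap(np.zeros(4), "m"), SpatialMap(np.zeros(4), "g"))
        p = build_regional_parameters(
            LinearCoefficients(c_w=0.5, c_I=0.3, c_sigma=0.01), *maps
        )
        assert np.allclose(p.w, 0.5) and np.allclose(p.I, 0.3) and np.allclose(p.sigma, 0.01)

    def test_identity_on_map(self):
        maps = (SpatialMap(np.array([1.0, 2.0, 3.0]), "m"), SpatialMap(np.zeros(3), "g"))
        p = build_regional_parameters(
            LinearCoefficients(a_w=1.0, c_sigma=0.01), *maps
        )
        assert np.allclose(p.w, [1, 2, 3])

    def test_nonpositive_sigma_rejected(self):
        maps = (SpatialMap(np.zeros(3), "m"), SpatialMap(np.zeros(3), "g"))
        with pytest.raises(InfeasibleParametersError):
            build_regional_parameters(LinearCoefficients(c_w=1.0), *maps)

    def test_parameter_counts(self):
        assert n_free_parameters(68, parametric=True) == 10
        assert n_free_parameters(68, parametric=False) == 205


def _two_region_sc():
    return Connectome(C=np.array([[0.0, 1e-12], [1e-12, 0.0]]))


class TestIntegrator:
    def test_fixed_point_matches_root_finder(self):
        """With sigma -> 0 and G = 0 the terminal state solves drift = 0."""
        sc = _two_region_sc()
        n = 2
        w, I = 1e-12, 0.4
        p = RegionalParameters(w=np.full(n, w), I=np.full(n, I), sigma=np.full(n, 1e-12), G=0.0)
        cfg = SimulationConfig(dt=0.01, t_total=20.0, t_burn=1.0, tr=0.72, seed=1)
        traj = integrate_mfm(p, sc, config=cfg, noise=np.zeros((n, cfg.n_steps)))
        s_terminal = traj.S[0, -1]
        s_star = brentq(lambda s: drift(s, w, I), 1e-6, 1 - 1e-6)
        assert s_terminal == pytest.approx(s_star, abs=1e-6)
        # closed form at x = 0.4: r*tau*H / (1 + r*tau*H)
        rt = CONST.r_kin * CONST.tau_s * transfer_function(0.4)
        assert s_terminal == pytest.approx(rt / (1 + rt), abs=1e-5)
        assert abs(drift(s_terminal, w, I)) < 1e-8

    def test_decay_to_low_state_with_zero_input(self):
        sc = _two_region_sc()
        p = RegionalParameters(w=np.full(2, 1e-12), I=np.full(2, 0.0),
                               sigma=np.full(2, 1e-12), G=0.0)
        cfg = SimulationConfig(dt=0.01, t_total=20.0, t_burn=1.0, tr=0.72, seed=1)
        traj = integrate_mfm(p, sc, config=cfg, noise=np.zeros((2, cfg.n_steps)))
        s_star = brentq(lambda s: drift(s, 1e-12, 0.0), 0.0, 0.5)
        assert traj.S[0, -1] == pytest.approx(s_star, abs=1e-6)
        assert traj.S[0, -1] < 1e-5

    def test_gating_bounded(self, small_sc, small_maps):
        p = build_regional_parameters(
            LinearCoefficients(c_w=1.0, c_I=0.35, c_sigma=0.2, G=1.0), *small_maps
        )
        cfg = SimulationConfig(dt=0.01, t_total=30.0, t_burn=1.0, tr=0.72, seed=7)
        traj = integrate_mfm(p, small_sc, config=cfg)
        assert traj.S.min() >= 0.0 and traj.S.max() <= 1.0

    def test_halving_dt_consistency(self):
        """Deterministic terminal state changes < 1e-4 when dt halves."""
        sc = _two_region_sc()
        p = RegionalParameters(w=np.full(2, 1.0), I=np.full(2, 0.3),
                               sigma=np.full(2, 1e-12), G=0.0)
        outs = []
        for dt in (0.01, 0.005):
            cfg = SimulationConfig(dt=dt, t_total=20.0, t_burn=1.0, tr=0.72, seed=1)
            traj = integrate_mfm(p, sc, config=cfg, noise=np.zeros((2, cfg.n_steps)))
            outs.append(traj.S[:, -1])
        assert np.max(np.abs(outs[0] - outs[1])) < 1e-4

    def test_dimension_mismatch(self, small_sc):
        p = RegionalParameters(w=np.ones(3), I=np.zeros(3), sigma=np.full(3, 0.01), G=0.0)
        with pytest.raises(InvalidInputError):
            integrate_mfm(p, small_sc)


class TestBalloonWindkessel:
    def test_zero_drive_stays_at_baseline(self):
        z = np.zeros((3, 500))
        bold = balloon_windkessel(NeuralTrajectory(S=z, dt=0.01))
        assert np.allclose(bold, 0.0, atol=1e-12)

    def test_identical_inputs_give_identical_outputs(self, rng):
        z1 = np.clip(0.3 + 0.05 * rng.standard_normal(800), 0, 1)
        z = np.vstack([z1, z1])
        bold = balloon_windkessel(NeuralTrajectory(S=z, dt=0.01))
        assert np.array_equal(bold[0], bold[1])

    def test_boxcar_returns_to_baseline(self):
        """A brief gating boxcar produces a BOLD excursion that decays back,
        matching a fine-step Euler oracle to 1e-4."""
        dt = 0.01
        K = 6000  # 60 s
        z = np.zeros((1, K))
        z[0, 100:200] = 0.5
        bold = balloon_windkessel(NeuralTrajectory(S=z, dt=dt))
        assert np.abs(bold[0]).max() > 1e-4          # an excursion happened
        assert abs(bold[0, -1]) < 0.01 * np.abs(bold[0]).max()  # returned within 1%
        # independent fine-step oracle (dt/10), sampled at the coarse grid
        hc = HemodynamicConstants()
        s = f = v = q = None
        s, f, v, q = 0.0, 1.0, 1.0, 1.0
        fine = [0.0]
        for k in range(1, K):
            zi = z[0, k - 1]
            for _ in range(10):
                ds = zi - hc.kappa * s - hc.gamma * (f - 1)
                df = s
                dv = (f - v ** (1 / hc.alpha)) / hc.tau
                E = 1 - (1 - hc.rho) ** (1 / f)
                dq = (f * E / hc.rho - v ** (1 / hc.alpha) * q / v) / hc.tau
                s, f, v, q = (s + dt / 10 * ds, f + dt / 10 * df,
                              v + dt / 10 * dv, q + dt / 10 * dq)
            fine.append(hc.V0 * (hc.k1 * (1 - q) + hc.k2 * (1 - q / v) + hc.k3 * (1 - v)))
        assert np.max(np.abs(bold[0] - np.array(fine))) < 1e-4


class TestSimulateBold:
    def test_default_protocol_frame_count(self):
        cfg = SimulationConfig()
        assert cfg.n_frames == 1200
        assert cfg.steps_per_frame == 72

    def test_short_protocol_output_shape(self, short_bold, short_config):
        assert short_bold.n_frames == short_config.n_frames
        assert short_bold.n_regions == 10
        assert short_bold.tr == 0.72

    def test_tr_not_multiple_of_dt_rejected(self):
        with pytest.raises(InvalidInputError):
            SimulationConfig(dt=0.01, tr=0.715)

    def test_seed_reproducibility(self, quiet_coeffs, small_sc, small_maps):
        cfg = SimulationConfig(dt=0.01, t_total=60.0, t_burn=10.0, tr=0.72, seed=42)
        b1 = simulate_bold(quiet_coeffs, small_sc, small_maps, config=cfg)
        b2 = simulate_bold(quiet_coeffs, small_sc, small_maps, config=cfg)
        assert np.array_equal(b1.B, b2.B)
        cfg2 = SimulationConfig(dt=0.01, t_total=60.0, t_burn=10.0, tr=0.72, seed=43)
        b3 = simulate_bold(quiet_coeffs, small_sc, small_maps, config=cfg2)
        assert not np.array_equal(b1.B, b3.B)


class TestConnectomeValidation:
    def test_asymmetric_rejected(self):
        C = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(InvalidInputError):
            Connectome(C=C)

    def test_negative_rejected(self):
        C = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(InvalidInputError):
            Connectome(C=C)

    def test_nonzero_diagonal_rejected(self):
        C = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(InvalidInputError):
            Connectome(C=C)
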