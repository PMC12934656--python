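import numpy as np
import pytest
from scipy.stats import multivariate_normal

from smtkit import pem_states as ps
from smtkit.core import AcquisitionParams
from smtkit.simulate import SimConfig, simulate_tracks

from .conftest import make_table

SLOW_ACQ = AcquisitionParams(frame_interval_s=0.2, exposure_s=0.01)


def make_subtracks(diffusivities, weights, n, sigma_um=0.03, seed=0, acq=SLOW_ACQ):
    """Direct sub-track sampler from the tridiagonal displacement covariance."""
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval_s
    blur = acq.exposure_s / dt / 6.0
    disp = np.empty((n, 2, 6))
    labels = rng.choice(len(diffusivities), size=n, p=np.asarray(weights))
    for j, d in enumerate(diffusivities):
        cov = np.zeros((6, 6))
        np.fill_diagonal(cov, 2 * d * dt + 2 * sigma_um**2 - 4 * d * blur * dt)
        for i in range(5):
            cov[i, i + 1] = cov[i + 1, i] = -(sigma_um**2) + 2 * d * blur * dt
        idx = np.flatnonzero(labels == j)
        draws = rng.multivariate_normal(np.zeros(6), cov, size=(len(idx), 2))
        disp[idx] = draws
    import pandas as pd

    pos = np.concatenate([np.zeros((n, 2, 1)), np.cumsum(disp, axis=2)], axis=2)
    meta = pd.DataFrame({"track_id": np.arange(n), "start_frame": 0})
    return (
        ps.SubTrackSet(disp_um=disp, pos_um=pos, meta=meta, dt_s=dt, exposure_s=acq.exposure_s),
        labels,
    )


class TestSplit:
    @pytest.mark.parametrize("n_frames,expected", [(16, 2), (6, 0), (7, 1), (14, 2)])
    def test_window_counts(self, n_frames, expected):
        t = make_table({0: [(f, float(f), 0.0) for f in range(n_frames)]}, acq=SLOW_ACQ)
        subs = ps.split_subtracks(t)
        assert len(subs) == expected

    def test_windows_are_nonoverlapping_and_consecutive(self):
        t = make_table({0: [(f, float(f), 0.0) for f in range(16)]}, acq=SLOW_ACQ)
        subs = ps.split_subtracks(t)
        assert list(subs.meta["start_frame"]) == [0, 7]
        # unit step in x per frame -> all displacements equal the pixel pitch
        assert np.allclose(subs.disp_um[:, 0, :], SLOW_ACQ.pixel_size_um)

    def test_split_length_validation(self):
        t = make_table({0: [(f, 0.0, 0.0) for f in range(10)]})
        with pytest.raises(ValueError):
            ps.split_subtracks(t, split_length=2)


class TestLikelihoodOracle:
    def test_dst_likelihood_equals_dense_mvn(self):
        """Tridiagonal-covariance likelihood vs brute-force dense evaluation."""
        rng = np.random.default_rng(5)
        subs, _ = make_subtracks([0.02], [1.0], 50, seed=1)
        u, cos = ps._sine_basis(6)
        z2 = np.sum(np.einsum("nad,dk->nak", subs.disp_um, u) ** 2, axis=1)
        dt, blur = subs.dt_s, subs.blur_coefficient
        for _ in range(10):
            d = float(np.exp(rng.uniform(np.log(1e-4), np.log(1.0))))
            sig = float(rng.uniform(0.01, 0.075))
            cov = np.zeros((6, 6))
            np.fill_diagonal(cov, 2 * d * dt + 2 * sig**2 - 4 * d * blur * dt)
            for i in range(5):
                cov[i, i + 1] = cov[i + 1, i] = -(sig**2) + 2 * d * blur * dt
            mvn = multivariate_normal(mean=np.zeros(6), cov=cov)
            dense = mvn.logpdf(subs.disp_um[:, 0, :]) + mvn.logpdf(subs.disp_um[:, 1, :])
            fast = ps._state_loglik(z2, d, sig**2, dt, blur, cos)
            assert np.abs(dense - fast).max() < 1e-8


class TestEMFit:
    def test_single_state_recovery(self):
        subs, _ = make_subtracks([0.01], [1.0], 5000, sigma_um=0.03, seed=2)
        m = ps.em_fit(subs, 1, seed=0)
        assert m.d_um2s[0] == pytest.approx(0.01, rel=0.1)
        assert m.sigma_um[0] == pytest.approx(0.03, rel=0.1)

    def test_two_state_mixture_recovery(self):
        subs, _ = make_subtracks([0.003, 0.08], [0.5, 0.5], 4000, seed=3)
        m = ps.em_fit(subs, 2, seed=1)
        assert m.pi[0] == pytest.approx(0.5, abs=0.05)
        assert m.d_um2s[0] == pytest.approx(0.003, rel=0.15)
        assert m.d_um2s[1] == pytest.approx(0.08, rel=0.15)

    def test_posteriors_rows_sum_to_one(self):
        subs, _ = make_subtracks([0.003, 0.08], [0.4, 0.6], 500, seed=4)
        m = ps.em_fit(subs, 2, seed=2)
        assert np.allclose(m.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(m.d_um2s) >= 0)  # states sorted by D

    def test_em_loglik_nondecreasing(self):
        subs, _ = make_subtracks([0.003, 0.08], [0.5, 0.5], 800, seed=5)
        # run EM step by step via increasing max_iter; loglik must not drop
        lls = [ps.em_fit(subs, 2, seed=3, max_iter=n, tol=0.0).log_likelihood
               for n in (1, 3, 10, 30)]
        assert all(b >= a - 1e-7 for a, b in zip(lls, lls[1:]))


class TestSelection:
    @pytest.mark.parametrize("dvals,weights,true_k", [
        ([0.01], [1.0], 1),
        ([0.002, 0.2], [0.5, 0.5], 2),
    ])
    def test_bic_selects_true_k(self, dvals, weights, true_k):
        subs, _ = make_subtracks(dvals, weights, 2500, seed=6)
        best = ps.select_model(subs, k_range=range(1, 4), n_reinit=3, n_perturb=10,
                               n_runs=1, seed=0, max_iter=500)
        assert best.k == true_k

    def test_k_range_of_one(self):
        subs, _ = make_subtracks([0.01], [1.0], 200, seed=7)
        best = ps.select_model(subs, k_range=[1], n_reinit=2, n_perturb=5, n_runs=1, seed=0)
        assert best.k == 1


class TestAssignment:
    def test_confident_assignment(self):
        m = ps.StateModel(k=2, d_um2s=np.array([0.01, 0.1]), sigma_um=np.array([0.03, 0.03]),
                          pi=np.array([0.5, 0.5]),
                          posteriors=np.array([[0.9, 0.1], [0.55, 0.45], [0.2, 0.8]]),
                          log_likelihood=0.0, bic=0.0, converged=True, n_iterations=1)
        labels = ps.assign_states(m, gap=0.2)
        assert list(labels) == [1, 0, 2]  # middle one unassigned

    def test_single_state_all_assigned(self):
        m = ps.StateModel(k=1, d_um2s=np.array([0.01]), sigma_um=np.array([0.03]),
                          pi=np.array([1.0]), posteriors=np.ones((5, 1)),
                          log_likelihood=0.0, bic=0.0, converged=True, n_iterations=1)
        assert (ps.assign_states(m) == 1).all()

    def test_normalized_fractions(self):
        labels = np.array([1] * 50 + [2] * 30 + [3] * 20)
        out = ps.normalized_state_fractions(labels, 3, f_bound=0.5, n_boot=20, seed=0)
        assert np.allclose(out["fraction"].to_numpy()[:3], [0.25, 0.15, 0.10])
        assert out[out["state"] == "unbound"]["fraction"].iloc[0] == pytest.approx(0.5)
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_fbound_one_identity(self):
        labels = np.array([1] * 60 + [2] * 40)
        out = ps.normalized_state_fractions(labels, 2, f_bound=1.0, n_boot=10, seed=0)
        assert np.allclose(out["fraction"].to_numpy(), [0.6, 0.4, 0.0])


class TestStateMSD:
    def test_states_separate_and_noise_floor(self):
        subs, labels_true = make_subtracks([0.0, 0.05], [0.5, 0.5], 2000,
                                           sigma_um=0.03, seed=8)
        msd = ps.state_msd(subs, labels_true + 1)
        m1 = msd[msd["state"] == 1]
        m2 = msd[msd["state"] == 2]
        assert (m2["msd_um2"].to_numpy() > m1["msd_um2"].to_numpy()).all()
        # immobile state: MSD plateau ~ 4 sigma^2 (no blur for D = 0)
        assert m1["msd_um2"].iloc[-1] == pytest.approx(4 * 0.03**2, rel=0.15)
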