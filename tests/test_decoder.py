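import math

import numpy as np
import pytest

from conftest import random_instance
from spikelattice.decoder import (Path, brute_force_decode, decode,
                                  ensemble_loglik, sequence_loglik,
                                  step_loglik)
from spikelattice.io import EventSet
from spikelattice.models import (ClusterParams, ModelSet,
                                 first_firing_loglik, lognormal_logpdf,
                                 lognormal_logsf)


class TestStepLoglik:
    def test_empty_path_uses_first_firing_branch(self, instance_factory, rng):
        ev, model = instance_factory(rng, K=2, N=3)
        s = step_loglik(ev.X[0], ev.z[0], 1, Path(), model)
        c = model.clusters[1]
        expected = (max(float(np.log(c.prior)), -745.0)
                    + first_firing_loglik(model.tau_win, c.beta))
        # remaining term is the gaussian; subtract and compare
        from spikelattice.models import gaussian_loglik
        assert s - gaussian_loglik(ev.X[0], c.mu_w, c.cov_w) == \
            pytest.approx(expected, abs=1e-9)

    def test_recent_occurrence_uses_isi_branch(self, instance_factory, rng):
        ev, model = instance_factory(rng, K=2, N=3)
        z_n = ev.z[1]
        path = Path(window=[(z_n - 0.001, 1)])
        c = model.clusters[1]
        from spikelattice.models import gaussian_loglik
        s = step_loglik(ev.X[1], z_n, 1, path, model)
        isi_term = lognormal_logpdf(0.001, c.mu_isi, c.var_isi)
        assert s == pytest.approx(
            gaussian_loglik(ev.X[1], c.mu_w, c.cov_w) + isi_term
            + math.log(c.prior), abs=1e-9)

    def test_accumulated_steps_match_sequence(self, instance_factory, rng):
        # the recursion and the direct statement of the objective agree
        for _ in range(20):
            ev, model = instance_factory(rng)
            labels = rng.integers(0, model.K, ev.n_events)
            path = Path()
            total = 0.0
            for n in range(ev.n_events):
                j = int(labels[n])
                path.window = [(t, l) for t, l in path.window
                               if t > ev.z[n] - model.tau_win]
                total += step_loglik(ev.X[n], ev.z[n], j, path, model)
                path.window.append((ev.z[n], j))
            assert total == pytest.approx(
                sequence_loglik(ev, labels, model), abs=1e-9)


class TestSequenceLoglik:
    def test_single_event(self, instance_factory, rng):
        ev, model = instance_factory(rng, K=2, N=2)
        one = EventSet(ev.z[:1], ev.X[:1])
        from spikelattice.models import gaussian_loglik
        c = model.clusters[0]
        expected = (gaussian_loglik(ev.X[0], c.mu_w, c.cov_w)
                    + first_firing_loglik(model.tau_win, c.beta)
                    + math.log(c.prior))
        assert sequence_loglik(one, [0], model) == pytest.approx(expected, abs=1e-9)

    def test_additivity_over_separated_segments(self, instance_factory, rng):
        ev, model = instance_factory(rng, K=2, N=4, tau=0.05)
        gap = model.tau_win * 3
        z2 = np.concatenate([ev.z, ev.z + ev.z[-1] + gap])
        X2 = np.vstack([ev.X, ev.X])
        labels = np.array([0, 1, 0, 1] * 2)
        both = sequence_loglik(EventSet(z2, X2), labels, model)
        single = sequence_loglik(ev, labels[:4], model)
        assert both == pytest.approx(2 * single, abs=1e-9)


class TestDecode:
    def test_k1_all_zero(self, instance_factory, rng):
        ev, model = instance_factory(rng, K=1, N=5)
        res = decode(ev, model, L=4)
        assert np.array_equal(res.labels, np.zeros(5, dtype=int))
        assert res.loglik == pytest.approx(
            sequence_loglik(ev, res.labels, model), abs=1e-9)

    def test_matches_brute_force_exhaustively(self, rng):
        # oracle equivalence at L = K^N on 200 random instances
        for _ in range(200):
            ev, model = random_instance(rng)
            K, N = model.K, ev.n_events
            bl, bll = brute_force_decode(ev, model)
            res = decode(ev, model, L=K ** N)
            assert np.array_equal(res.labels, bl)
            assert res.loglik == pytest.approx(bll, abs=1e-9)

    def test_beam_monotone_in_L(self, rng):
        for _ in range(20):
            ev, model = random_instance(rng, K=3, N=6)
            lls = [decode(ev, model, L=L).loglik for L in (1, 10, 100, 3 ** 6)]
            assert all(a <= b + 1e-12 for a, b in zip(lls, lls[1:]))

    def test_permutation_equivariance(self, rng):
        for _ in range(20):
            ev, model = random_instance(rng, K=3, N=5)
            perm = rng.permutation(3)
            res = decode(ev, model, L=3 ** 5)
            res_p = decode(ev, model.permuted(perm), L=3 ** 5)
            # new cluster i = old cluster perm[i]: labels map via inverse
            inv = np.argsort(perm)
            assert np.array_equal(inv[res.labels], res_p.labels)
            assert res.loglik == pytest.approx(res_p.loglik, abs=1e-9)

    def test_self_consistency(self, rng):
        for _ in range(30):
            ev, model = random_instance(rng)
            res = decode(ev, model, L=7)
            assert res.loglik == pytest.approx(
                sequence_loglik(ev, res.labels, model), abs=1e-9)

    def test_separable_construction_zero_errors(self, rng):
        # two far-apart waveform clusters with disjoint ISI regimes
        n = 50
        labels = rng.integers(0, 2, n)
        X = np.where(labels[:, None] == 0, -10.0, 10.0) + rng.normal(0, 0.3, (n, 2))
        z = np.cumsum(rng.uniform(0.005, 0.02, n))
        cl = [
            ClusterParams([-10, -10], np.eye(2) * 0.1, math.log(0.012), 0.2, 25.0, 0.5),
            ClusterParams([10, 10], np.eye(2) * 0.1, math.log(0.012), 0.2, 25.0, 0.5),
        ]
        model = ModelSet(cl, tau_win=0.3, L=100)
        res = decode(EventSet(z, X), model)
        assert np.array_equal(res.labels, labels) or \
            np.array_equal(res.labels, 1 - labels)

    def test_invalid_L(self, instance_factory, rng):
        ev, model = instance_factory(rng)
        with pytest.raises(ValueError):
            decode(ev, model, L=0)


class TestBruteForce:
    def test_single_event_argmax(self, instance_factory, rng):
        ev, model = instance_factory(rng, K=3, N=2)
        one = EventSet(ev.z[:1], ev.X[:1])
        bl, bll = brute_force_decode(one, model)
        scores = [sequence_loglik(one, [j], model) for j in range(3)]
        assert bl[0] == int(np.argmax(scores))
        assert bll == pytest.approx(max(scores), abs=1e-12)

    def test_label_permutation_symmetry(self, rng):
        ev, model = random_instance(rng, K=3, N=4)
        perm = np.array([2, 0, 1])
        bl, bll = brute_force_decode(ev, model)
        bl_p, bll_p = brute_force_decode(ev, model.permuted(perm))
        inv = np.argsort(perm)
        assert np.array_equal(inv[bl], bl_p)
        assert bll == pytest.approx(bll_p, abs=1e-9)

    def test_too_large_raises(self, rng):
        ev, model = random_instance(rng, K=3, N=3)
        big = EventSet(np.arange(1, 20) * 0.01, np.zeros((19, 2)))
        with pytest.raises(ValueError):
            brute_force_decode(big, model)


class TestEnsembleLoglik:
    def test_two_event_expansion(self):
        c = ClusterParams([0.0], [[1.0]], math.log(0.02), 0.5, 10.0, 1.0)
        model = ModelSet([c], tau_win=0.1)
        z = np.array([0.05, 0.08])
        ev = EventSet(z, np.zeros((2, 1)))
        T = 0.5
        expected = (math.log(10.0 * 0.05) - 10.0 * 0.05
                    + lognormal_logpdf(0.03, c.mu_isi, c.var_isi)
                    + lognormal_logsf(T - 0.08, c.mu_isi, c.var_isi)
                    + 2 * math.log(1.0))
        assert ensemble_loglik(ev, [0, 0], model, T) == \
            pytest.approx(expected, abs=1e-10)

    def test_survival_monotone_in_T(self):
        c = ClusterParams([0.0], [[1.0]], math.log(0.02), 0.5, 10.0, 1.0)
        model = ModelSet([c], tau_win=0.1)
        ev = EventSet([0.05, 0.08], np.zeros((2, 1)))
        vals = [ensemble_loglik(ev, [0, 0], model, T) for T in (0.1, 1.0, 10.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_differs_from_sequence_by_survival_and_w_terms(self):
        # term-by-term comparison on a 3-event single-cluster instance
        c = ClusterParams([0.0], [[1.0]], math.log(0.02), 0.5, 10.0, 1.0)
        model = ModelSet([c], tau_win=1e6)  # window never truncates
        z = np.array([0.05, 0.08, 0.11])
        ev = EventSet(z, np.zeros((3, 1)))
        T = 0.5
        seq = sequence_loglik(ev, [0, 0, 0], model)
        ens = ensemble_loglik(ev, [0, 0, 0], model, T)
        # the two differ by: the waveform terms (decoding objective only),
        # the survival term (full-train only), and the first-firing argument
        # (w at tau_win, floored, vs w at the actual first firing time)
        w_seq = math.log(10.0 * 1e6) - 10.0 * 1e6
        w_ens = math.log(10.0 * 0.05) - 10.0 * 0.05
        surv = lognormal_logsf(T - z[-1], c.mu_isi, c.var_isi)
        gauss = 3 * (-0.5 * math.log(2 * math.pi))
        assert ens - seq == pytest.approx(
            (w_ens - max(w_seq, -745.0)) + surv - gauss, abs=1e-9)

    def test_empty_cluster_warns(self):
        c = ClusterParams([0.0], [[1.0]], math.log(0.02), 0.5, 10.0, 0.5)
        model = ModelSet([c, c], tau_win=0.1)
        ev = EventSet([0.05], np.zeros((1, 1)))
        with pytest.warns(UserWarning):
            ensemble_loglik(ev, [0], model, 1.0)
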