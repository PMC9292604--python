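"""Coalescent HMM: interval patterns, binarization, exact likelihoods,
EM behaviour, scaling and bootstrap."""

import itertools

import numpy as np
import pytest

from chelonia.core import CallableMask
from chelonia.smc import (
    HET,
    HOM,
    MISSING,
    BinSequence,
    SmcConfig,
    SmcTrajectory,
    binarize_positions,
    bootstrap,
    build_transition,
    equilibrium_distribution,
    fit_smc,
    parse_interval_pattern,
    representative_times,
    scale_trajectory,
    time_boundaries,
    _backward,
    _forward,
)


class TestIntervalPattern:
    def test_msmc_style_pattern(self):
        n, groups = parse_interval_pattern("4+25*2+4+6")
        assert n == 64
        assert len(groups) == 28
        assert groups == [4] + [2] * 25 + [4] + [6]

    def test_repeated_singletons(self):
        assert parse_interval_pattern("1*4") == (4, [4])

    @pytest.mark.parametrize("bad", ["0+2", "", "2+", "x*2", "-1"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_interval_pattern(bad)


class TestBinarize:
    def test_no_hets_full_mask_all_hom(self):
        mask = CallableMask.full({"s": 1000})
        seq = binarize_positions({"s": np.array([], dtype=np.int64)}, mask, {"s": 1000}, 10)
        assert np.all(seq.symbols["s"] == HOM)
        assert len(seq.symbols["s"]) == 100

    def test_single_difference_lands_in_expected_bin(self):
        mask = CallableMask.full({"s": 1000})
        for p in (1, 10, 11, 995):
            seq = binarize_positions({"s": np.array([p])}, mask, {"s": 1000}, 10)
            sym = seq.symbols["s"]
            expected_bin = (p - 1) // 10
            assert sym[expected_bin] == HET
            assert np.sum(sym == HET) == 1

    def test_toy_sequence_with_mask_gap_hand_binned(self):
        # 200 bp, bin 20; diffs at 5, 45, 130; mask gap [40, 100)
        mask = CallableMask({"s": np.array([[0, 40], [100, 200]])})
        seq = binarize_positions({"s": np.array([5, 45, 130])}, mask, {"s": 200}, 20)
        sym = seq.symbols["s"]
        # bins 2-4 (spans 40-100) are >50% uncallable -> missing, overriding het at 45
        expected = [HET, HOM, MISSING, MISSING, MISSING, HOM, HET, HOM, HOM, HOM]
        assert sym.tolist() == expected

    def test_half_masked_bin_rule(self):
        # bin 10: exactly half callable -> missing (cov <= 0.5*span)
        mask = CallableMask({"s": np.array([[0, 5]])})
        seq = binarize_positions({"s": np.array([], dtype=np.int64)}, mask, {"s": 10}, 10)
        assert seq.symbols["s"][0] == MISSING


def small_model(K=3, t_max=4.0, lam=(0.7, 1.3, 1.0), rho=0.05, theta=0.1):
    b = time_boundaries(K, t_max)
    lam = np.asarray(lam, dtype=float)
    t = representative_times(b, lam)
    A, pi = build_transition(b, lam, rho, t)
    E = np.empty((3, K))
    E[HOM] = np.exp(-theta * t)
    E[HET] = -np.expm1(-theta * t)
    E[MISSING] = 1.0
    return b, lam, t, A, pi, E


class TestHmmExactness:
    def test_transition_rows_and_prior_normalized(self):
        for K, lam in [(3, (0.7, 1.3, 1.0)), (8, tuple(np.linspace(0.4, 2.5, 8)))]:
            b = time_boundaries(K, 10.0)
            lam = np.asarray(lam)
            t = representative_times(b, lam)
            A, pi = build_transition(b, lam, 0.02, t)
            assert np.abs(A.sum(axis=1) - 1).max() < 1e-12
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(A > 0) and np.all(pi > 0)

    def test_forward_equals_exhaustive_path_sum(self):
        _, _, _, A, pi, E = small_model()
        sym = np.array([0, 1, 0, 0, 2, 1, 0, 0, 1, 0, 0, 2], dtype=np.int8)
        total = 0.0
        for path in itertools.product(range(3), repeat=len(sym)):
            p = pi[path[0]] * E[sym[0], path[0]]
            for i in range(1, len(sym)):
                p *= A[path[i - 1], path[i]] * E[sym[i], path[i]]
            total += p
        alpha, c = _forward(sym, pi, A, E)
        assert np.sum(np.log(c)) == pytest.approx(np.log(total), abs=1e-8)

    def test_forward_backward_consistency(self):
        _, _, _, A, pi, E = small_model(K=5, lam=tuple(np.linspace(0.5, 2, 5)))
        rng = np.random.default_rng(3)
        sym = rng.choice([0, 0, 0, 1, 2], size=400).astype(np.int8)
        alpha, c = _forward(sym, pi, A, E)
        beta = _backward(sym, A, E, c)
        # posterior marginals sum to one at every bin
        gamma = alpha * beta
        assert np.abs(gamma.sum(axis=1) - 1).max() < 1e-8
        # backward recomputation of the total likelihood
        ll_f = np.sum(np.log(c))
        ll_b = np.log(np.sum(pi * E[sym[0]] * beta[0])) + np.sum(np.log(c[1:]))
        assert ll_b == pytest.approx(ll_f, rel=1e-8)

    def test_missing_block_bridges_markov_dynamics(self):
        _, _, _, A, pi, E = small_model()
        left = np.array([0, 1, 0], dtype=np.int8)
        right = np.array([1, 0, 0], dtype=np.int8)
        k = 4
        sym = np.concatenate([left, np.full(k, MISSING, dtype=np.int8), right])
        alpha, c = _forward(sym, pi, A, E)
        ll = np.sum(np.log(c))
        # manual bridge: run forward over the left flank, propagate through
        # A^k with unit emissions, continue over the right flank
        a = pi * E[left[0]]
        lik = a.sum()
        a = a / lik
        ll_manual = np.log(lik)
        for s in left[1:]:
            a = (a @ A) * E[s]
            ll_manual += np.log(a.sum())
            a = a / a.sum()
        a = a @ np.linalg.matrix_power(A, k)
        for s in right:
            a = (a @ A) * E[s]
            ll_manual += np.log(a.sum())
            a = a / a.sum()
        assert ll == pytest.approx(ll_manual, abs=1e-8)


class TestFit:
    def _toy_seq(self, n=30_000, seed=0, theta=0.08):
        # symbols drawn from the model's own equilibrium at lam=1
        rng = np.random.default_rng(seed)
        sym = (rng.random(n) < theta / (1 + theta)).astype(np.int8)
        sym[rng.random(n) < 0.02] = MISSING
        return BinSequence(symbols={"s": sym}, bin_size=100)

    def test_em_loglik_non_decreasing(self):
        seqs = self._toy_seq()
        cfg = SmcConfig(bin_size=100, pattern="4*2", t_max=8.0, max_iters=8, min_bins=1000)
        traj = fit_smc(seqs, cfg)
        ll = np.array(traj.loglik_trace)
        assert len(ll) >= 2
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_deterministic_given_inputs(self):
        seqs = self._toy_seq()
        cfg = SmcConfig(bin_size=100, pattern="4*2", t_max=8.0, max_iters=4, min_bins=1000)
        t1 = fit_smc(seqs, cfg)
        t2 = fit_smc(seqs, cfg)
        assert np.array_equal(t1.lam, t2.lam) and t1.theta == t2.theta

    def test_no_het_bins_rejected(self):
        seqs = BinSequence(symbols={"s": np.zeros(20_000, dtype=np.int8)}, bin_size=100)
        with pytest.raises(ValueError, match="degenerate|het"):
            fit_smc(seqs, SmcConfig(bin_size=100))

    def test_too_few_bins_rejected(self):
        seqs = BinSequence(symbols={"s": np.ones(100, dtype=np.int8)}, bin_size=100)
        with pytest.raises(ValueError, match="bins"):
            fit_smc(seqs, SmcConfig(bin_size=100, min_bins=10_000))


def make_traj(lam_groups, theta=0.0316, bin_size=100, t_max=15.0):
    groups = [1] * len(lam_groups)
    b = time_boundaries(len(lam_groups), t_max)
    return SmcTrajectory(
        boundaries=b,
        lam=np.asarray(lam_groups, dtype=float),
        groups=groups,
        theta=theta,
        rho=theta / 2,
        bin_size=bin_size,
    )


class TestScaling:
    def test_known_n0_scaling(self):
        # theta chosen so N0 = theta/(4*mu*bin) = 10,000
        mu, bin_size = 7.9e-9, 100
        theta = 4 * 10_000 * mu * bin_size
        traj = make_traj([1.0] * 8, theta=theta, bin_size=bin_size)
        sc = scale_trajectory(traj, mu, gen_time=1.0)
        # times in generations equal 2*N0*t_coal
        assert np.allclose(sc.left_years, traj.boundaries[:-1] * 2 * 10_000)
        assert np.allclose(sc["Ne"], 10_000)

    def test_gen_time_linearity(self):
        traj = make_traj([1.0, 2.0, 0.5, 1.0, 1.0, 1.0])
        a = scale_trajectory(traj, 7.9e-9, 10.0)
        b = scale_trajectory(traj, 7.9e-9, 20.0)
        assert np.allclose(b.left_years, 2 * a.left_years)
        assert np.allclose(b["Ne"], a["Ne"])

    def test_lambda_round_trip(self):
        traj = make_traj([0.5, 1.0, 2.0, 1.0, 1.0, 3.0])
        sc = scale_trajectory(traj, 7.9e-9, 24.0)
        n0 = traj.n0(7.9e-9)
        assert np.allclose(n0 / sc["Ne"].to_numpy(), traj.lam)

    def test_zero_theta_rejected(self):
        traj = make_traj([1.0] * 6, theta=1e-9)
        traj.theta = 0.0
        with pytest.raises(ValueError, match="theta"):
            traj.n0(7.9e-9)


class TestBinSequenceIO:
    def test_text_round_trip(self, tmp_path):
        from chelonia.smc import read_bin_sequence, write_bin_sequence

        rng = np.random.default_rng(8)
        seqs = BinSequence(
            symbols={
                "a": rng.choice([0, 1, 2], size=500).astype(np.int8),
                "b": rng.choice([0, 1, 2], size=37).astype(np.int8),
            },
            bin_size=10,
        )
        p = tmp_path / "bins.txt"
        write_bin_sequence(seqs, p)
        back = read_bin_sequence(p)
        assert back.bin_size == 10
        for k in seqs.symbols:
            assert np.array_equal(back.symbols[k], seqs.symbols[k])


class TestBootstrap:
    def _seqs(self):
        rng = np.random.default_rng(2)
        sym = (rng.random(40_000) < 0.05).astype(np.int8)
        return BinSequence(symbols={"s": sym}, bin_size=100)

    def test_identity_replicate_equals_point_fit(self):
        seqs = self._seqs()
        cfg = SmcConfig(bin_size=100, pattern="4*2", t_max=8.0, max_iters=3, min_bins=1000)
        point = fit_smc(seqs, cfg)
        (rep,) = bootstrap(seqs, cfg, n_reps=1, segment=1_000_000, resample=False)
        assert np.array_equal(rep.lam, point.lam)
        assert rep.theta == point.theta

    def test_same_seed_identical_replicates(self):
        seqs = self._seqs()
        cfg = SmcConfig(bin_size=100, pattern="4*2", t_max=8.0, max_iters=2, min_bins=1000)
        r1 = bootstrap(seqs, cfg, n_reps=2, segment=1_000_000, seed=5)
        r2 = bootstrap(seqs, cfg, n_reps=2, segment=1_000_000, seed=5)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.lam, b.lam)

    def test_segment_longer_than_genome_rejected(self):
        seqs = self._seqs()
        cfg = SmcConfig(bin_size=100, pattern="4*2", max_iters=1, min_bins=1000)
        with pytest.raises(ValueError, match="segment"):
            bootstrap(seqs, cfg, n_reps=1, segment=100_000_000)
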