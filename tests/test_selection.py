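"""Haplotype segments, HEBV/H-score/S-score, usefulness and intensity —
including brute-force oracle equivalence on randomized small instances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepscope import (
    GenomeLayout,
    PVector,
    build_segments,
    h_score,
    h_scores,
    hebv_matrix,
    pairwise_hebv,
    predict_progeny_mean_sd,
    s_score,
    selection_intensity,
    usefulness,
)
from deepscope.selection import segments_from_counts, s_scores

# ----------------------------------------------------------------- oracles


def brute_force_hebv_matrix(X, beta, segments):
    H = np.zeros((X.shape[0], len(segments)))
    for h in range(X.shape[0]):
        for j, (a, b) in enumerate(segments):
            for m in range(a, b):
                H[h, j] += X[h, m] * beta[m]
    return H


def brute_force_pairwise(i, j, H, lam):
    total = 0.0
    for s in range(H.shape[1]):
        total += max(H[2 * i, s], H[2 * i + 1, s], H[2 * j, s], H[2 * j + 1, s])
    return lam * total


def brute_force_s_score(zi, zj, p, divisor=2.0):
    return sum((zi[m] - zj[m]) ** 2 / divisor * p[m] for m in range(len(zi)))


# ---------------------------------------------------------------- segments


class TestBuildSegments:
    def test_exact_single_window(self):
        sm = segments_from_counts([20], window=20, step=5)
        assert sm.segments == [(0, 20)]

    def test_enumerated_starts_25_markers(self):
        sm = segments_from_counts([25], window=20, step=5)
        assert sm.segments == [(0, 20), (5, 25)]

    def test_short_chromosome_truncated_segment(self):
        sm = segments_from_counts([10], window=20, step=5)
        assert sm.segments == [(0, 10)]

    def test_end_anchored_final_window(self):
        sm = segments_from_counts([23], window=20, step=5)
        assert sm.segments == [(0, 20), (3, 23)]

    def test_every_marker_covered(self):
        sm = segments_from_counts([20, 33, 7], window=20, step=5)
        covered = np.zeros(60, dtype=bool)
        for a, b in sm.segments:
            covered[a:b] = True
        assert covered.all()
        # windows never span chromosomes
        bounds = [(0, 20), (20, 53), (53, 60)]
        for (a, b), c in zip(sm.segments, sm.segment_chrom):
            lo, hi = bounds[c]
            assert lo <= a and b <= hi

    def test_lambda_default(self):
        sm = segments_from_counts([40], window=20, step=5)
        assert sm.lam == 0.25

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            segments_from_counts([30], window=20, step=25)

    def test_from_layout_counts(self, small_layout):
        sm = build_segments(small_layout, window=5, step=2)
        assert sm.n_markers == small_layout.n_markers

    def test_membership_matrix_definition(self):
        sm = segments_from_counts([12], window=5, step=3)
        M = sm.membership_matrix()
        for j, (a, b) in enumerate(sm.segments):
            assert np.array_equal(np.flatnonzero(M[:, j]), np.arange(a, b))


# --------------------------------------------------------------- toy HEBV

TOY_BETA = np.array([1.0, 2.0, 3.0, 4.0])
TOY_SEGMENTS = segments_from_counts([4], window=2, step=2)  # {1-2}, {3-4}
TOY_X = np.array(
    [
        [1, 0, 1, 0],  # i hap 1
        [0, 1, 0, 0],  # i hap 2
        [0, 0, 0, 1],  # j hap 1
        [1, 1, 0, 0],  # j hap 2
    ],
    dtype=float,
)


class TestPairwiseHebv:
    def test_worked_toy_example(self):
        H = hebv_matrix(TOY_X, TOY_BETA, TOY_SEGMENTS)
        assert pairwise_hebv(0, 1, H, lam=1.0) == pytest.approx(7.0)

    def test_self_pair_toy(self):
        H = hebv_matrix(TOY_X, TOY_BETA, TOY_SEGMENTS)
        assert pairwise_hebv(0, 0, H, lam=1.0) == pytest.approx(5.0)

    def test_symmetry(self):
        H = hebv_matrix(TOY_X, TOY_BETA, TOY_SEGMENTS)
        assert pairwise_hebv(0, 1, H) == pairwise_hebv(1, 0, H)

    def test_step_equals_window_reduces_to_ohv(self, rng):
        """With lambda = 1 and non-overlapping windows, HEBV(i,i) is the OHV:
        sum over segments of the better haplotype value."""
        k = 12
        beta = rng.normal(size=k)
        sm = segments_from_counts([k], window=4, step=4)
        X = rng.integers(0, 2, size=(2, k)).astype(float)
        H = hebv_matrix(X, beta, sm)
        ohv = sum(
            max((X[0, a:b] * beta[a:b]).sum(), (X[1, a:b] * beta[a:b]).sum())
            for a, b in sm.segments
        )
        assert pairwise_hebv(0, 0, H) == pytest.approx(ohv)
        # and it dominates the better-haplotype GEBV by construction of max
        gebv_best = max((X[0] * beta).sum(), (X[1] * beta).sum())
        assert pairwise_hebv(0, 0, H) >= gebv_best - 1e-12


class TestHScore:
    def test_single_elite_toy(self):
        H = hebv_matrix(TOY_X, TOY_BETA, TOY_SEGMENTS)
        assert h_score(0, [1], H, lam=1.0) == pytest.approx(7.0)

    def test_self_elite_toy(self):
        H = hebv_matrix(TOY_X, TOY_BETA, TOY_SEGMENTS)
        assert h_score(0, [0], H, lam=1.0) == pytest.approx(5.0)

    def test_enlarging_elite_never_decreases(self, rng):
        k = 8
        X = rng.integers(0, 2, size=(10, k)).astype(float)
        H = hebv_matrix(X, rng.normal(size=k), segments_from_counts([k], 4, 2))
        small = h_score(0, [1, 2], H)
        large = h_score(0, [1, 2, 3, 4], H)
        assert large >= small - 1e-12

    def test_empty_elite_rejected(self):
        H = hebv_matrix(TOY_X, TOY_BETA, TOY_SEGMENTS)
        with pytest.raises(ValueError):
            h_score(0, [], H)


class TestSScore:
    def test_identical_genotypes_zero(self):
        z = np.array([1, 0, -1])
        assert s_score(z, z, np.ones(3)) == 0.0

    def test_worked_example(self):
        zi = np.array([1, 0, -1])
        zj = np.array([-1, 0, -1])
        assert s_score(zi, zj, np.ones(3)) == pytest.approx(2.0)

    def test_full_masking_zero(self, rng):
        zi = rng.integers(-1, 2, size=10)
        zj = rng.integers(-1, 2, size=10)
        assert s_score(zi, zj, np.zeros(10)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            s_score(np.zeros(3), np.zeros(4), np.ones(4))

    def test_additive_over_disjoint_subsets(self, rng):
        zi = rng.integers(-1, 2, size=12)
        zj = rng.integers(-1, 2, size=12)
        p = np.ones(12)
        left, right = p.copy(), p.copy()
        left[6:] = 0
        right[:6] = 0
        assert s_score(zi, zj, p) == pytest.approx(
            s_score(zi, zj, left) + s_score(zi, zj, right)
        )


class TestPVector:
    def test_single_homozygote_leaves_mask(self):
        p = PVector(4)
        p.update(np.array([-1, -1, -1, -1]))
        assert np.all(p.values == 1)

    def test_opposite_homozygotes_clear_mask(self):
        p = PVector(4)
        p.update(np.full(4, -1))
        p.update(np.full(4, 1))
        assert np.all(p.values == 0)

    def test_heterozygote_clears_immediately(self):
        p = PVector(3)
        p.update(np.array([0, 1, -1]))
        assert p.values.tolist() == [0, 1, 1]

    def test_monotone_non_increasing(self, rng):
        p = PVector(20)
        prev = p.values.copy()
        for _ in range(10):
            p.update(rng.integers(-1, 2, size=20))
            now = p.values
            assert np.all(now <= prev)
            prev = now


class TestUsefulness:
    def test_zero_spread_returns_mean(self):
        assert usefulness(3.2, 0.0) == 3.2

    def test_direct_substitution(self):
        assert usefulness(10.0, 2.0, i=2.06, rho=1.0) == pytest.approx(14.12)

    def test_zero_intensity_reduces_to_mean_selection(self):
        assert usefulness(5.0, 4.0, i=0.0) == 5.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            usefulness(1.0, -0.1)


class TestSelectionIntensity:
    def test_five_percent_tail(self):
        assert selection_intensity(0.05) == pytest.approx(2.063, abs=1e-3)

    def test_no_selection_limit(self):
        assert selection_intensity(0.999999) < 1e-4

    def test_monotone_decreasing(self):
        fracs = [0.01, 0.05, 0.2, 0.5, 0.9]
        vals = [selection_intensity(f) for f in fracs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_enforced(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                selection_intensity(bad)


class TestProgenyMeanSd:
    def test_selfing_an_inbred_has_zero_spread(self, small_layout, rng):
        hap = rng.integers(0, 2, size=(small_layout.n_loci,)).astype(np.int8)
        parent = np.stack([hap, hap])
        u = rng.normal(size=small_layout.n_markers)
        mu, sd = predict_progeny_mean_sd(parent, parent, u, small_layout, 50, rng)
        z = hap[small_layout.marker_indices] * 2.0 - 1.0
        assert sd == pytest.approx(0.0, abs=1e-10)
        assert mu == pytest.approx(float(z @ u))

    def test_single_segregating_marker_matches_f3_enumeration(self, rng):
        """Parents differing at one marker: the F3 genotype at that marker is
        -1/0/+1 with probabilities 3/8, 1/4, 3/8, so the progeny SD is
        beta * sqrt(3/4)."""
        layout = GenomeLayout(
            chrom_lengths=[100.0],
            loci_per_chromosome=[2],
            positions=[30.0, 70.0],
            chrom_of=[0, 0],
            qtl_indices=[0],
            marker_indices=[1],
        )
        p1 = np.array([[0, 0], [0, 0]], dtype=np.int8)
        p2 = np.array([[0, 1], [0, 1]], dtype=np.int8)
        beta = np.array([1.7])
        mus, sds = [], []
        for _ in range(40):
            mu, sd = predict_progeny_mean_sd(p1, p2, beta, layout, 200, rng)
            mus.append(mu)
            sds.append(sd)
        # E[Z] = 0, Var[Z] = 3/4 under the F3 distribution
        assert abs(np.mean(mus)) < 0.05
        assert np.mean(sds) == pytest.approx(1.7 * np.sqrt(3 / 4), rel=0.03)

    def test_more_virtual_progeny_reduces_monte_carlo_error(self, small_layout, rng):
        p1 = rng.integers(0, 2, size=(2, small_layout.n_loci)).astype(np.int8)
        p2 = rng.integers(0, 2, size=(2, small_layout.n_loci)).astype(np.int8)
        u = rng.normal(size=small_layout.n_markers)
        small = [predict_progeny_mean_sd(p1, p2, u, small_layout, 50, rng)[1] for _ in range(12)]
        large = [predict_progeny_mean_sd(p1, p2, u, small_layout, 400, rng)[1] for _ in range(12)]
        assert np.std(large) < np.std(small)


# ------------------------------------------------- randomized oracle suite

hyp_settings = settings(max_examples=60, deadline=None, derandomize=True)


@hyp_settings
@given(data=st.data())
def test_hebv_matrix_matches_bruteforce(data):
    """H = (X o 1 beta') M equals the naive double-loop segment summation."""
    k = data.draw(st.integers(4, 12))
    n = data.draw(st.integers(1, 4))
    window = data.draw(st.integers(1, k))
    step = data.draw(st.integers(1, window))
    seed = data.draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(2 * n, k)).astype(float)
    beta = rng.normal(size=k)
    sm = segments_from_counts([k], window, step)
    H = hebv_matrix(X, beta, sm)
    assert np.allclose(H.values, brute_force_hebv_matrix(X, beta, sm.segments))


@hyp_settings
@given(data=st.data())
def test_h_and_pairwise_scores_match_bruteforce(data):
    """Vectorized H-scores equal exhaustive max-over-elites recomputation."""
    k = data.draw(st.integers(6, 12))
    n = data.draw(st.integers(2, 6))
    seed = data.draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(2 * n, k)).astype(float)
    beta = rng.normal(size=k)
    sm = segments_from_counts([k], window=4, step=2)
    H = hebv_matrix(X, beta, sm)
    elites = list(range(1, n))
    for i in range(n):
        oracle = max(brute_force_pairwise(i, j, H.values, sm.lam) for j in elites)
        assert h_score(i, elites, H) == pytest.approx(oracle)
    B = H.segment_max()
    batch = h_scores(B, B[elites], sm.lam)
    for i in range(n):
        oracle = max(brute_force_pairwise(i, j, H.values, sm.lam) for j in elites)
        assert batch[i] == pytest.approx(oracle)


@hyp_settings
@given(data=st.data())
def test_s_score_matches_bruteforce_and_is_symmetric(data):
    k = data.draw(st.integers(1, 15))
    seed = data.draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    zi = rng.integers(-1, 2, size=k)
    zj = rng.integers(-1, 2, size=k)
    p = rng.integers(0, 2, size=k).astype(float)
    got = s_score(zi, zj, p)
    assert got == pytest.approx(brute_force_s_score(zi, zj, p))
    assert got == pytest.approx(s_score(zj, zi, p))
    assert got >= 0
    batch = s_scores(zi, np.stack([zj, zi]), p)
    assert batch[0] == pytest.approx(got)
    assert batch[1] == pytest.approx(0.0)


@hyp_settings
@given(divisor=st.sampled_from([2.0, 4.0]), seed=st.integers(0, 2**16))
def test_s_score_divisor_choice_preserves_argmax(divisor, seed):
    """The two-point variance denominator rescales scores by a constant and
    cannot change which partner is selected."""
    rng = np.random.default_rng(seed)
    zi = rng.integers(-1, 2, size=10)
    cands = rng.integers(-1, 2, size=(6, 10))
    p = np.ones(10)
    a = s_scores(zi, cands, p, divisor=2.0)
    b = s_scores(zi, cands, p, divisor=divisor)
    assert np.array_equal(np.argsort(a, kind="stable"), np.argsort(b, kind="stable"))
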