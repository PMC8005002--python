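"""Phi-ST / Fst, SHD, PCA and classical MDS.

The Phi-ST oracle recomputes the two-group AMOVA with explicit double
loops over individuals, written independently of the vectorized
implementation.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop.core import Population, Sample
from mitopop.haplogroups import MajorHgScheme
from mitopop.popgen import (
    DistanceMatrix,
    classical_mds,
    fst_permutation_test,
    pairwise_difference_matrix,
    pca,
    phi_st,
    phi_st_matrix,
    shared_hg_report,
    shd,
    shd_matrix,
    slatkin_linearize,
)
from tests.conftest import make_population


# ---------------------------------------------------------------------------
# independent AMOVA oracle


def differences(a: str, b: str) -> int:
    count = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT" and x != y:
            count += 1
    return count


def amova_phi_st_oracle(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Two-group AMOVA Phi-ST via explicit double-loop sums of squares."""
    pooled = seqs_a + seqs_b
    n_total = len(pooled)
    n_a, n_b = len(seqs_a), len(seqs_b)

    ss_total = 0.0
    for i in range(n_total):
        for j in range(n_total):
            ss_total += differences(pooled[i], pooled[j])
    ss_total /= 2 * n_total

    ss_within = 0.0
    for group in (seqs_a, seqs_b):
        acc = 0.0
        for i in range(len(group)):
            for j in range(len(group)):
                acc += differences(group[i], group[j])
        ss_within += acc / (2 * len(group))

    ss_among = ss_total - ss_within
    sigma_w = ss_within / (n_total - 2)
    n_prime = (n_total - (n_a * n_a + n_b * n_b) / n_total) / (2 - 1)
    sigma_a = (ss_among / (2 - 1) - sigma_w) / n_prime
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


def random_instance(rng: np.random.Generator, length: int = 30):
    """A random two-population instance with <= 12 sequences total."""
    n_a = int(rng.integers(2, 7))
    n_b = int(rng.integers(2, 7))
    # draw from a small haplotype pool so groups share sequences sometimes
    pool = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(4)]
    seqs_a = [pool[int(rng.integers(0, 4))] for _ in range(n_a)]
    seqs_b = [pool[int(rng.integers(0, 4))] for _ in range(n_b)]
    return seqs_a, seqs_b


class TestPairwiseDifferences:
    def test_identical(self):
        a = make_population("a", sequences=["AAAA", "AAAA"])
        b = make_population("b", sequences=["AAAA"])
        assert pairwise_difference_matrix(a, b).tolist() == [[0], [0]]

    def test_direct_count(self):
        a = make_population("a", sequences=["AAAA"])
        b = make_population("b", sequences=["AAGG"])
        assert pairwise_difference_matrix(a, b)[0, 0] == 2

    def test_missing_positions_skipped(self):
        a = make_population("a", sequences=["AANA"])
        b = make_population("b", sequences=["AAGG"])
        assert pairwise_difference_matrix(a, b)[0, 0] == 1

    def test_length_mismatch(self):
        a = make_population("a", sequences=["AAAA"])
        b = make_population("b", sequences=["AAAAA"])
        with pytest.raises(ValueError, match="length"):
            pairwise_difference_matrix(a, b)


class TestPhiSt:
    def test_identical_populations_give_zero(self):
        seq = "ACGTACGT" * 4
        assert phi_st(make_population("a", sequences=[seq] * 3),
                      make_population("b", sequences=[seq] * 4)) == 0.0

    def test_fixed_differences_give_one(self):
        x = "A" * 40
        y = "C" * 5 + "A" * 35
        assert phi_st(make_population("a", sequences=[x] * 3),
                      make_population("b", sequences=[y] * 2)) == pytest.approx(1.0)

    def test_small_population_rejected(self):
        x = "A" * 20
        with pytest.raises(ValueError, match="at least 2"):
            phi_st(make_population("a", sequences=[x]),
                   make_population("b", sequences=[x, x]))

    def test_matches_oracle_on_fixture(self):
        seqs_a = ["AAAA", "AAAT", "AATT", "AAAA"]
        seqs_b = ["TTAA", "TTAT", "TTTT", "TTAA"]
        expected = amova_phi_st_oracle(seqs_a, seqs_b)
        got = phi_st(make_population("a", sequences=seqs_a),
                     make_population("b", sequences=seqs_b))
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            seqs_a, seqs_b = random_instance(rng)
            expected = amova_phi_st_oracle(seqs_a, seqs_b)
            got = phi_st(make_population("a", sequences=seqs_a),
                         make_population("b", sequences=seqs_b))
            assert got == pytest.approx(expected, abs=1e-10)


class TestSlatkin:
    @pytest.mark.parametrize("fst,expected", [(0.0, 0.0), (0.5, 1.0), (0.0098, 0.009897)])
    def test_closed_form(self, fst, expected):
        assert slatkin_linearize(fst) == pytest.approx(expected, abs=5e-7)

    def test_negative_passes_through(self):
        value = slatkin_linearize(-0.01)
        assert value == pytest.approx(-0.01 / 1.01)

    def test_one_gives_infinity_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isinf(slatkin_linearize(1.0))


class TestPermutationTest:
    def test_determinism(self):
        rng = np.random.default_rng(0)
        seqs_a, seqs_b = random_instance(rng)
        a = make_population("a", sequences=seqs_a)
        b = make_population("b", sequences=seqs_b)
        r1 = fst_permutation_test(a, b, n_permutations=200, seed=42)
        r2 = fst_permutation_test(a, b, n_permutations=200, seed=42)
        assert r1.p_value == r2.p_value and r1.fst == r2.fst

    def test_strong_structure_is_significant(self):
        x = "A" * 40
        y = "C" * 10 + "A" * 30
        a = make_population("a", sequences=[x] * 5)
        b = make_population("b", sequences=[y] * 5)
        # only 2 of C(10,5) = 252 group relabelings separate the two fixed
        # haplotypes, so p concentrates near 2/252 ~ 0.008
        result = fst_permutation_test(a, b, n_permutations=9999, seed=1)
        assert result.p_value <= 0.01

    def test_null_is_not_significant(self):
        rng = np.random.default_rng(5)
        pool = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(3)]
        seqs = [pool[int(rng.integers(0, 3))] for _ in range(16)]
        a = make_population("a", sequences=seqs[:8])
        b = make_population("b", sequences=seqs[8:])
        result = fst_permutation_test(a, b, n_permutations=499, seed=2)
        assert result.p_value >= 0.05

    def test_degenerate_pool_warns_and_returns_one(self):
        seq = "ACGT" * 5
        a = make_population("a", sequences=[seq] * 3)
        b = make_population("b", sequences=[seq] * 3)
        with pytest.warns(UserWarning, match="identical"):
            result = fst_permutation_test(a, b, n_permutations=99, seed=0)
        assert result.p_value == 1.0

    def test_p_value_never_zero(self):
        x = "A" * 40
        y = "C" * 10 + "A" * 30
        a = make_population("a", sequences=[x] * 3)
        b = make_population("b", sequences=[y] * 3)
        result = fst_permutation_test(a, b, n_permutations=999, seed=9)
        assert 0 < result.p_value <= 1


class TestShd:
    def test_identical_profiles_give_zero(self):
        a = make_population("a", ["T1a1", "H", "H", "T1a1"])
        b = make_population("b", ["H", "T1a1", "T1a1", "H"])
        assert shd(a, b) == pytest.approx(0.0)

    def test_disjoint_profiles_give_one(self):
        a = make_population("a", ["H1a", "U5a"])
        b = make_population("b", ["C4a1", "D4e4"])
        assert shd(a, b) == pytest.approx(1.0)

    def test_min_overlap_sum(self):
        # A = {T1a1: 0.5, H: 0.5}, B = {T1a1: 0.25, U5a: 0.75}
        a = make_population("a", ["T1a1", "T1a1", "H", "H"])
        b = make_population("b", ["T1a1", "U5a", "U5a", "U5a"])
        assert shd(a, b) == pytest.approx(0.75)

    def test_symmetric_and_bounded(self):
        a = make_population("a", ["H1", "H1", "U5a", "T2b", "K1a"])
        b = make_population("b", ["H1", "C4a1", "C4a1", "T2b"])
        assert shd(a, b) == pytest.approx(shd(b, a))
        assert 0 <= shd(a, b) <= 1
        assert shd(a, a) == 0.0

    @given(
        st.lists(st.sampled_from(["H1", "U5a", "T2b", "C4a1"]), min_size=1, max_size=12),
        st.lists(st.sampled_from(["H1", "U5a", "T2b", "C4a1"]), min_size=1, max_size=12),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_one_minus_shd_is_total_variation_overlap(self, hgs_a, hgs_b):
        from collections import Counter

        a = make_population("a", hgs_a)
        b = make_population("b", hgs_b)
        fa = Counter(hgs_a)
        fb = Counter(hgs_b)
        support = set(fa) | set(fb)
        # overlap = 1 - TV distance
        tv = 0.5 * sum(abs(fa[h] / len(hgs_a) - fb[h] / len(hgs_b)) for h in support)
        assert 1 - shd(a, b) == pytest.approx(1 - tv, abs=1e-12)

    def test_matrix_is_valid_distance_matrix(self):
        pops = [
            make_population("a", ["H1", "U5a"]),
            make_population("b", ["H1", "C4a1"]),
            make_population("c", ["T2b"]),
        ]
        matrix = shd_matrix(pops)
        assert matrix.labels == ("a", "b", "c")
        assert matrix.values[0, 1] == pytest.approx(0.5)


class TestSharedHgReport:
    def test_disjoint_populations_empty(self):
        report = shared_hg_report(make_population("a", ["H1"]), make_population("b", ["U5a"]))
        assert report == []

    def test_shared_east_lineage_flagged(self):
        a = make_population("a", ["N1a1a1a1a", "H7"])
        b = make_population("b", ["N1a1a1a1a", "H7", "U5a"])
        report = shared_hg_report(a, b)
        by_hg = {r.haplogroup: r for r in report}
        assert set(by_hg) == {"N1a1a1a1a", "H7"}
        # N1a1a1a1a reduces to N1a, not in the default east set
        assert by_hg["N1a1a1a1a"].east_eurasian is False
        assert by_hg["H7"].east_eurasian is False
        assert by_hg["H7"].freq_a == pytest.approx(0.5)

    def test_east_flag_follows_scheme(self):
        scheme = MajorHgScheme(classes=("N1a", "H"), east_set=frozenset({"N1a"}))
        a = make_population("a", ["N1a1a1a1a", "H7"])
        b = make_population("b", ["N1a1a1a1a"])
        (entry,) = shared_hg_report(a, b, scheme)
        assert entry.east_eurasian is True


class TestPca:
    def test_two_populations_single_axis(self):
        import pandas as pd

        table = pd.DataFrame([[0.6, 0.4], [0.2, 0.8]], index=["a", "b"], columns=["H", "U"])
        result = pca(table, k=1)
        assert result.explained[0] == pytest.approx(1.0)

    def test_duplicated_rows_identical_coordinates(self):
        import pandas as pd

        table = pd.DataFrame(
            [[0.6, 0.4], [0.2, 0.8], [0.6, 0.4]], index=["a", "b", "a2"], columns=["H", "U"]
        )
        result = pca(table, k=1)
        assert result.coordinates.loc["a", "PC1"] == pytest.approx(
            result.coordinates.loc["a2", "PC1"]
        )

    def test_axis_variances_match_covariance_eigendecomposition(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        x = rng.dirichlet(np.ones(6), size=5)
        table = pd.DataFrame(x, index=[f"p{i}" for i in range(5)])
        k = 4
        result = pca(table, k=k)
        # brute-force oracle: eigenvalues of the biased covariance matrix
        centered = x - x.mean(axis=0)
        cov = centered.T @ centered
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fractions = eigvals / eigvals.sum()
        np.testing.assert_allclose(result.explained, fractions[:k], atol=1e-9)
        # scores reproduce total variance axis by axis
        score_var = (result.coordinates.to_numpy() ** 2).sum(axis=0)
        np.testing.assert_allclose(score_var, eigvals[:k], atol=1e-9)

    def test_k_too_large_rejected(self):
        import pandas as pd

        table = pd.DataFrame([[0.5, 0.5], [0.3, 0.7]], index=["a", "b"])
        with pytest.raises(ValueError, match="k"):
            pca(table, k=2)  # max is n_pops - 1 = 1

    def test_sign_convention_deterministic(self):
        import pandas as pd

        table = pd.DataFrame(
            [[0.6, 0.4], [0.2, 0.8], [0.5, 0.5]], index=["a", "b", "c"], columns=["H", "U"]
        )
        r1 = pca(table, k=1)
        r2 = pca(table.copy(), k=1)
        assert (r1.coordinates == r2.coordinates).all().all()


class TestClassicalMds:
    def test_collinear_points_embed_exactly_in_1d(self):
        dist = DistanceMatrix(labels=("a", "b", "c"),
                              values=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float))
        result = classical_mds(dist, k=1)
        coords = result.coordinates.to_numpy()
        for i in range(3):
            for j in range(3):
                got = abs(coords[i, 0] - coords[j, 0])
                assert got == pytest.approx(dist.values[i, j], abs=1e-9)

    def test_unit_square_recovered_in_2d(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dist = DistanceMatrix(labels=("a", "b", "c", "d"), values=d)
        result = classical_mds(dist, k=2)
        coords = result.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_eigenvalues_descending(self):
        pts = np.array([[0, 0], [3, 0], [0, 4], [5, 5]], dtype=float)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        result = classical_mds(DistanceMatrix(labels=tuple("abcd"), values=d), k=3)
        assert list(result.explained) == sorted(result.explained, reverse=True)

    def test_label_permutation_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = tuple(f"p{i}" for i in range(6))
        perm = rng.permutation(6)
        d_perm = d[np.ix_(perm, perm)]
        r1 = classical_mds(DistanceMatrix(labels=labels, values=d), k=3)
        r2 = classical_mds(
            DistanceMatrix(labels=tuple(labels[i] for i in perm), values=d_perm), k=3
        )
        # embeddings agree up to rotation/reflection: compare distance matrices
        c1 = r1.coordinates.loc[list(labels)].to_numpy()
        c2 = r2.coordinates.loc[list(labels)].to_numpy()
        d1 = np.sqrt(((c1[:, None, :] - c1[None, :, :]) ** 2).sum(-1))
        d2 = np.sqrt(((c2[:, None, :] - c2[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_non_euclidean_input_warns(self):
        # violates the triangle inequality strongly enough for a negative eigenvalue
        d = np.array([[0, 10, 1], [10, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="negative"):
            classical_mds(DistanceMatrix(labels=tuple("abc"), values=d), k=2)

    def test_all_zero_matrix_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            classical_mds(DistanceMatrix(labels=tuple("abc"), values=d), k=1)

    def test_eckart_young_round_trip_on_linearized_fst(self):
        """Embedding Gram matrix equals the top-k spectral truncation of the
        double-centered input (Eckart-Young)."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(5, 4))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dist = DistanceMatrix(labels=tuple(f"p{i}" for i in range(5)), values=d)
        k = 2
        result = classical_mds(dist, k=k)
        coords = result.coordinates.to_numpy()
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        eigval, eigvec = np.linalg.eigh(b)
        order = np.argsort(eigval)[::-1][:k]
        b_k = (eigvec[:, order] * eigval[order]) @ eigvec[:, order].T
        np.testing.assert_allclose(coords @ coords.T, b_k, atol=1e-9)


class TestDistanceMatrix:
    def test_csv_round_trip(self, tmp_path):
        values = np.array([[0, 0.1], [0.1, 0]])
        matrix = DistanceMatrix(labels=("a", "b"), values=values)
        path = tmp_path / "d.csv"
        matrix.to_csv(path)
        loaded = DistanceMatrix.from_csv(path)
        assert loaded.labels == ("a", "b")
        np.testing.assert_allclose(loaded.values, values)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(labels=("a",), values=np.array([[1.0]]))

    def test_phi_st_matrix_clamps_negatives_when_linearizing(self):
        rng = np.random.default_rng(4)
        pool = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(3)]
        pops = [
            make_population(name, sequences=[pool[int(rng.integers(0, 3))] for _ in range(5)])
            for name in ("a", "b", "c")
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            linearized = phi_st_matrix(pops, linearize=True)
        assert (linearized.values >= 0).all()
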