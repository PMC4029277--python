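"""Minwise hashing, additional hashing, and compact fingerprint laws."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from cpihash import (
    EmptySetError,
    UndefinedSimilarityError,
    ValidationError,
    additional_hash,
    collision_probability,
    compact_fingerprint,
    encode_pairs,
    jaccard,
    make_hash_family,
    minhash_value,
    pair_set,
)
from cpihash.minhash import min_under_permutation


class TestHashFamily:
    def test_determinism(self):
        f1 = make_hash_family(ell=5, M=32, N=8, master_seed=3)
        f2 = make_hash_family(ell=5, M=32, N=8, master_seed=3)
        for k in range(5):
            assert np.array_equal(f1.permutation(k), f2.permutation(k))
        ts = np.arange(32)
        assert np.array_equal(f1.additional_hash(ts), f2.additional_hash(ts))

    def test_explicit_mode_yields_bijections(self):
        fam = make_hash_family(ell=4, M=8, N=4, master_seed=0)
        for k in range(4):
            assert sorted(fam.permutation(k).tolist()) == list(range(8))

    def test_different_seeds_differ(self):
        f1 = make_hash_family(ell=3, M=64, N=8, master_seed=0)
        f2 = make_hash_family(ell=3, M=64, N=8, master_seed=1)
        assert any(
            not np.array_equal(f1.permutation(k), f2.permutation(k)) for k in range(3)
        )

    def test_universal_mode_is_injective(self):
        fam = make_hash_family(ell=3, M=100, N=10, master_seed=2, mode="universal_hash")
        xs = np.arange(100)
        for k in range(3):
            assert np.unique(fam.apply_permutation(k, xs)).size == 100

    def test_validation(self):
        with pytest.raises(ValidationError):
            make_hash_family(ell=2, M=8, N=9, master_seed=0)  # N > M
        with pytest.raises(ValidationError):
            make_hash_family(ell=0, M=8, N=4, master_seed=0)
        with pytest.raises(ValidationError):
            make_hash_family(ell=2, M=0, N=0, master_seed=0)

    def test_serialization_round_trip(self):
        fam = make_hash_family(ell=3, M=50, N=7, master_seed=9, mode="universal_hash")
        from cpihash import HashFamily

        back = HashFamily.from_dict(fam.to_dict())
        assert back == fam
        assert np.array_equal(
            back.apply_permutation(1, np.arange(50)),
            fam.apply_permutation(1, np.arange(50)),
        )

    def test_collision_rate_tracks_jaccard(self, random_sets):
        """Fraction of matching raw minhash coordinates estimates J."""
        s1, s2 = random_sets(m=16, min_size=3, max_size=12)
        j = jaccard(s1, s2)
        fam = make_hash_family(ell=2000, M=16, N=16, master_seed=5)
        t1 = fam.signature(np.array(sorted(s1))).values
        t2 = fam.signature(np.array(sorted(s2))).values
        rate = (t1 == t2).mean()
        sigma = np.sqrt(j * (1 - j) / 2000)
        assert abs(rate - j) <= 3 * sigma + 1e-12


class TestMinhashValue:
    def test_printed_worked_example(self):
        # permutation (1..8) -> (3,8,7,1,2,6,4,5); S = {1,4,6,7}; min image 1
        perm = np.array([3, 8, 7, 1, 2, 6, 4, 5]) - 1
        s = {x - 1 for x in (1, 4, 6, 7)}
        assert min_under_permutation(perm, s) + 1 == 1

    def test_matches_explicit_min_over_permuted_set(self):
        fam = make_hash_family(ell=3, M=16, N=16, master_seed=1)
        s = {5, 2, 9}
        for k in range(3):
            expected = min(fam.permutation(k)[x] for x in s)
            assert minhash_value(s, k, fam) == expected

    def test_singleton(self):
        fam = make_hash_family(ell=2, M=10, N=10, master_seed=0)
        assert minhash_value({5}, 0, fam) == fam.permutation(0)[5]

    def test_empty_set_raises(self):
        fam = make_hash_family(ell=2, M=10, N=10, master_seed=0)
        with pytest.raises(EmptySetError):
            minhash_value(set(), 0, fam)


class TestJaccard:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [({3, 9}, {3, 9}, 1.0), ({1, 2}, {3, 4}, 0.0), ({1, 2, 3}, {2, 3, 4}, 0.5)],
    )
    def test_known_values(self, s1, s2, expected):
        assert jaccard(s1, s2) == expected

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            jaccard(set(), set())


class TestAdditionalHash:
    def test_identical_inputs_always_collide(self):
        fam = make_hash_family(ell=2, M=100, N=8, master_seed=4)
        for t in range(100):
            assert additional_hash(t, fam) == additional_hash(t, fam)
            assert 0 <= additional_hash(t, fam) < 8

    def test_identity_mode(self):
        fam = make_hash_family(ell=2, M=16, N=16, master_seed=0, identity_h=True)
        for t in range(16):
            assert additional_hash(t, fam) == t

    def test_out_of_range_rejected(self):
        fam = make_hash_family(ell=2, M=16, N=4, master_seed=0)
        with pytest.raises(ValidationError):
            additional_hash(16, fam)
        with pytest.raises(ValidationError):
            additional_hash(-1, fam)

    def test_distinct_inputs_collide_at_one_over_n(self):
        """Pairs of distinct values collide at about rate 1/N."""
        m, n_bins = 2**20, 16
        fam = make_hash_family(ell=1, M=m, N=n_bins, master_seed=7)
        rng = np.random.default_rng(0)
        t1 = rng.integers(0, m, size=100_000)
        t2 = rng.integers(0, m, size=100_000)
        distinct = t1 != t2
        h1 = fam.additional_hash(t1[distinct])
        h2 = fam.additional_hash(t2[distinct])
        rate = (h1 == h2).mean()
        p = 1.0 / n_bins
        sigma = np.sqrt(p * (1 - p) / distinct.sum())
        assert abs(rate - p) <= 3 * sigma


class TestCollisionProbability:
    @pytest.mark.parametrize(
        "j, n, expected",
        [(1.0, 7, 1.0), (0.0, 16, 0.0625), (0.5, 2, 0.75)],
    )
    def test_known_values(self, j, n, expected):
        assert collision_probability(j, n) == pytest.approx(expected)

    def test_invalid_jaccard(self):
        with pytest.raises(ValidationError):
            collision_probability(1.5, 4)

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 10**6))
    def test_monotone_in_jaccard(self, j1, j2, n):
        lo, hi = sorted((j1, j2))
        assert collision_probability(lo, n) <= collision_probability(hi, n) + 1e-15

    @given(st.floats(0, 1))
    def test_saturation_toward_jaccard(self, j):
        """Beyond a few hundred bins the law is flat and approaches J."""
        assert abs(
            collision_probability(j, 2**16) - collision_probability(j, 2**32)
        ) < 1e-4
        assert abs(collision_probability(j, 2**32) - j) < 1e-6


class TestCompactFingerprint:
    def test_dense_expansion_rule(self):
        from cpihash.minhash import CompactFingerprint

        cf = CompactFingerprint(bins=np.array([2, 0]), n_bins=4)
        assert cf.to_dense().tolist() == [0, 0, 1, 0, 1, 0, 0, 0]
        assert cf.column_indices().tolist() == [2, 4]

    def test_degenerate_hash_reduces_to_minhash(self, tiny_dataset):
        fam = make_hash_family(ell=1, M=30, N=30, master_seed=3, identity_h=True)
        ps = pair_set(tiny_dataset.compounds["c0"], tiny_dataset.proteins["p0"])
        cf = compact_fingerprint(ps, fam)
        assert cf.bins[0] == minhash_value(set(ps.members.tolist()), 0, fam)

    def test_empty_pair_raises_with_ids(self, tiny_dataset):
        from cpihash import BinaryFingerprint
        from cpihash.fingerprints import PairFeatureSet

        ps = PairFeatureSet("cX", "pY", 6, 5, np.array([], dtype=np.int64))
        fam = make_hash_family(ell=2, M=30, N=5, master_seed=0)
        with pytest.raises(EmptySetError) as exc:
            compact_fingerprint(ps, fam)
        assert exc.value.pair == ("cX", "pY")

    def test_collision_law_monte_carlo(self, random_sets):
        """Matching-bin rate follows 1 - ((N-1)/N)(1-J) within 3 sigma."""
        s1, s2 = random_sets(m=200, min_size=20, max_size=60)
        j = jaccard(s1, s2)
        ell, n_bins = 3000, 64
        fam = make_hash_family(ell=ell, M=200, N=n_bins, master_seed=8)
        b1 = fam.compact(np.array(sorted(s1))).bins
        b2 = fam.compact(np.array(sorted(s2))).bins
        rate = (b1 == b2).mean()
        p = collision_probability(j, n_bins)
        sigma = np.sqrt(p * (1 - p) / ell)
        assert abs(rate - p) <= 3 * sigma


class TestEncodePairs:
    def test_rows_have_exactly_ell_ones(self, tiny_dataset):
        fam = make_hash_family(ell=6, M=30, N=5, master_seed=2)
        x, y, ids, skipped = encode_pairs(tiny_dataset, fam)
        assert x.shape == (8, 30)
        assert (x.sum(axis=1) == 6).all()
        assert skipped == []
        # one hit inside each consecutive block of N
        for row in range(x.shape[0]):
            blocks = x[row].indices // 5
            assert sorted(blocks.tolist()) == list(range(6))

    def test_rows_match_per_pair_compacts(self, tiny_dataset):
        fam = make_hash_family(ell=4, M=30, N=7, master_seed=6)
        x, _, ids, _ = encode_pairs(tiny_dataset, fam)
        for row, ps in enumerate(tiny_dataset.pair_sets()):
            cf = compact_fingerprint(ps, fam)
            assert sorted(x[row].indices.tolist()) == sorted(
                cf.column_indices().tolist()
            )

    def test_empty_pair_policy(self, tiny_dataset):
        compounds = dict(tiny_dataset.compounds)
        from cpihash import BinaryFingerprint

        compounds["cz"] = BinaryFingerprint("cz", 6, ())
        from cpihash import InteractionDataset

        ds = InteractionDataset(
            compounds=compounds,
            proteins=tiny_dataset.proteins,
            pairs=tiny_dataset.pairs + [("cz", "p0", -1)],
        )
        fam = make_hash_family(ell=2, M=30, N=5, master_seed=0)
        with pytest.raises(EmptySetError):
            encode_pairs(ds, fam)
        x, y, ids, skipped = encode_pairs(ds, fam, skip_empty=True)
        assert skipped == [("cz", "p0")]
        assert x.shape[0] == 8


class TestKernelProperties:
    def test_gram_matrix_is_psd(self, random_sets):
        pairs = random_sets(m=150, n_pairs=25, min_size=5, max_size=30)
        sets = [s for pair in pairs for s in pair]  # 50 sets
        fam = make_hash_family(ell=50, M=150, N=16, master_seed=9)
        rows = np.stack([fam.compact(np.array(sorted(s))).to_dense() for s in sets])
        gram = rows @ rows.T
        eigs = np.linalg.eigvalsh(gram.astype(float))
        assert eigs.min() >= -1e-8

    def test_inner_product_rank_correlates_with_jaccard(self, random_sets):
        pairs = random_sets(m=150, n_pairs=120, min_size=5, max_size=40)
        fam = make_hash_family(ell=100, M=150, N=32, master_seed=10)
        inner, jac = [], []
        for s1, s2 in pairs:
            b1 = fam.compact(np.array(sorted(s1))).bins
            b2 = fam.compact(np.array(sorted(s2))).bins
            inner.append((b1 == b2).mean())
            jac.append(jaccard(s1, s2))
        rho = spearmanr(inner, jac).statistic
        assert rho > 0

    def test_hamming_distance_law(self, random_sets):
        """Without additional hashing, E[Hamming] = ell * (1 - J)."""
        s1, s2 = random_sets(m=64, min_size=10, max_size=40)
        j = jaccard(s1, s2)
        ell = 2000
        fam = make_hash_family(ell=ell, M=64, N=64, master_seed=11, identity_h=True)
        t1 = fam.compact(np.array(sorted(s1))).bins
        t2 = fam.compact(np.array(sorted(s2))).bins
        hamming = (t1 != t2).sum()
        expected = ell * (1 - j)
        sigma = np.sqrt(ell * j * (1 - j))
        assert abs(hamming - expected) <= 3 * sigma + 1e-9
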