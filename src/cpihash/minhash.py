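"""Minwise hashing, additional hashing, and compact fingerprints.

A set S over a universe of size M is sketched by ``ell`` random
permutations pi_k of the universe: the k-th minhash value is
``min(pi_k(S))``.  Two sets collide on coordinate k with probability equal
to their Jaccard similarity J, so the expected Hamming distance between two
signatures is ``ell * (1 - J)``.

Storing raw minhash values costs a machine word each.  The additional
hashing stage maps each value through a random hash h into the small range
[0, N): identical minhash values still always collide, differing ones
collide with probability 1/N, giving the per-coordinate collision law

    P(collision) = 1 - ((N - 1) / N) * (1 - J).

Each hashed value is finally one-hot expanded into an N-bit block; the
concatenation over the ell blocks is the "compact fingerprint", an ell*N
binary vector with exactly ell ones, suitable as a sparse input row for a
linear classifier.

Two realizations of the permutations are provided:

* ``explicit_permutation`` — each pi_k is a seeded uniform random
  permutation of [0, M), materialized as an array.  Exact theory; intended
  for M up to ~2**24.
* ``universal_hash`` — pi_k(x) = (a_k * x + b_k) mod p, with p the
  smallest prime >= M and a_k != 0.  An injective approximation for
  universes too large to permute explicitly (e.g. M ~ 3.6 million tensor
  features); minhash values then live in [0, p).

A family is fully reconstructible from (ell, M, N, master_seed, mode):
per-permutation seeds are derived from (master_seed, k) and the h seed from
(master_seed, ell), so one master seed reproduces every stage, which is
what makes model serialization and weight recovery possible without
storing M-sized tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .exceptions import (
    EmptySetError,
    UndefinedSimilarityError,
    ValidationError,
)
from .fingerprints import InteractionDataset, PairFeatureSet

__all__ = [
    "HashFamily",
    "MinHashSignature",
    "CompactFingerprint",
    "make_hash_family",
    "jaccard",
    "minhash_value",
    "additional_hash",
    "collision_probability",
    "compact_fingerprint",
    "encode_pairs",
]

_EXPLICIT_LIMIT = 1 << 24

MODES = ("explicit_permutation", "universal_hash")


def _next_prime(n: int) -> int:
    """Smallest prime >= n (trial division; fine for n up to ~2**32)."""
    if n <= 2:
        return 2
    candidate = n if n % 2 else n + 1
    while True:
        is_prime = True
        d = 3
        while d * d <= candidate:
            if candidate % d == 0:
                is_prime = False
                break
            d += 2
        if is_prime:
            return candidate
        candidate += 2


def _derived_rng(master_seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


@dataclass(frozen=True)
class MinHashSignature:
    """Length-ell vector of raw minhash values."""

    values: np.ndarray

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class CompactFingerprint:
    """Length-ell vector of additional-hash bins, each in [0, N)."""

    bins: np.ndarray
    n_bins: int

    def __len__(self) -> int:
        return int(self.bins.size)

    def to_dense(self) -> np.ndarray:
        """One-hot expansion: an ell*N 0/1 vector with exactly ell ones."""
        ell = len(self)
        dense = np.zeros(ell * self.n_bins, dtype=np.int8)
        dense[np.arange(ell) * self.n_bins + self.bins] = 1
        return dense

    def column_indices(self) -> np.ndarray:
        """Sparse column indices ``k*N + bins[k]`` of the dense form."""
        return np.arange(len(self), dtype=np.int64) * self.n_bins + self.bins


@dataclass(frozen=True)
class HashFamily:
    """ell seeded permutations of [0, M) plus a 2-universal hash into [0, N).

    ``identity_h=True`` replaces h by the identity (requires N equal to the
    minhash value range); useful for studying the pure-minhash regime where
    the Hamming distance law holds without additional-hash collisions.
    """

    ell: int
    M: int
    N: int
    master_seed: int
    mode: str = "explicit_permutation"
    identity_h: bool = False

    # lazy caches; not part of identity/serialization
    _perm_cache: dict = field(
        default_factory=dict, repr=False, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if self.ell < 1:
            raise ValidationError(f"ell must be >= 1, got {self.ell}")
        if self.M < 1:
            raise ValidationError(f"M must be >= 1, got {self.M}")
        if self.N < 1:
            raise ValidationError(f"N must be >= 1, got {self.N}")
        if self.N > self.M:
            raise ValidationError(f"N={self.N} must not exceed M={self.M}")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.master_seed < 0:
            raise ValidationError("master_seed must be nonnegative")
        if self.mode == "explicit_permutation" and self.M > _EXPLICIT_LIMIT:
            raise ValidationError(
                f"M={self.M} too large for explicit permutations; "
                "use mode='universal_hash'"
            )
        if self.identity_h and self.N != self.value_range:
            raise ValidationError(
                "identity_h requires N equal to the minhash value range "
                f"({self.value_range})"
            )

    # -- permutation stage -------------------------------------------------

    @property
    def value_range(self) -> int:
        """Exclusive upper bound of raw minhash values.

        M for explicit permutations; the prime modulus p >= M for the
        affine universal-hash approximation.
        """
        if self.mode == "explicit_permutation":
            return self.M
        return self._universal_params()[2]

    def _universal_params(self) -> tuple[np.ndarray, np.ndarray, int]:
        cached = self._perm_cache.get("universal")
        if cached is None:
            p = _next_prime(self.M)
            a = np.empty(self.ell, dtype=np.int64)
            b = np.empty(self.ell, dtype=np.int64)
            for k in range(self.ell):
                rng = _derived_rng(self.master_seed, k)
                a[k] = rng.integers(1, p)
                b[k] = rng.integers(0, p)
            cached = (a, b, p)
            self._perm_cache["universal"] = cached
        return cached

    def _perm_matrix(self) -> np.ndarray:
        """All ell explicit permutations as an (ell, M) array."""
        cached = self._perm_cache.get("perms")
        if cached is None:
            cached = np.empty((self.ell, self.M), dtype=np.int64)
            for k in range(self.ell):
                cached[k] = _derived_rng(self.master_seed, k).permutation(self.M)
            self._perm_cache["perms"] = cached
        return cached

    def permutation(self, k: int) -> np.ndarray:
        """The image array of pi_k (explicit mode only)."""
        self._check_k(k)
        if self.mode != "explicit_permutation":
            raise ValidationError("permutation arrays exist only in explicit mode")
        return self._perm_matrix()[k]

    def _check_k(self, k: int) -> None:
        if not 0 <= k < self.ell:
            raise ValidationError(f"permutation index {k} out of range [0, {self.ell})")

    def apply_permutation(self, k: int, xs: np.ndarray) -> np.ndarray:
        """pi_k applied elementwise to universe indices ``xs``."""
        self._check_k(k)
        xs = np.asarray(xs, dtype=np.int64)
        if xs.size and (xs.min() < 0 or xs.max() >= self.M):
            raise ValidationError(f"universe index out of range [0, {self.M})")
        if self.mode == "explicit_permutation":
            return self._perm_matrix()[k][xs]
        a, b, p = self._universal_params()
        return (a[k] * xs + b[k]) % p

    # -- additional-hash stage ---------------------------------------------

    def _h_seed(self) -> np.uint64:
        cached = self._perm_cache.get("h")
        if cached is None:
            rng = _derived_rng(self.master_seed, self.ell)
            cached = np.uint64(rng.integers(0, 2**63))
            self._perm_cache["h"] = cached
        return cached

    def additional_hash(self, t: int | np.ndarray) -> int | np.ndarray:
        """h(t): map raw minhash value(s) into [0, N).

        Realized as a seeded 64-bit bit-mixing hash (splitmix64 finalizer)
        reduced mod N.  A fixed affine map modulo a prime is 2-universal
        but shares its linear structure across all minhash coordinates,
        which visibly biases the per-coordinate collision law; the mixer
        behaves like an independent uniform random function instead.
        """
        scalar = np.isscalar(t)
        ts = np.asarray(t, dtype=np.int64)
        if ts.size and (ts.min() < 0 or ts.max() >= self.value_range):
            raise ValidationError(
                f"minhash value out of range [0, {self.value_range})"
            )
        if self.identity_h:
            out = ts
        else:
            with np.errstate(over="ignore"):
                z = ts.astype(np.uint64) + self._h_seed()
                z = (z + np.uint64(0x9E3779B97F4A7C15)) * np.uint64(0xBF58476D1CE4E5B9)
                z ^= z >> np.uint64(27)
                z *= np.uint64(0x94D049BB133111EB)
                z ^= z >> np.uint64(31)
            out = (z % np.uint64(self.N)).astype(np.int64)
        return int(out) if scalar else out

    # -- sketching ----------------------------------------------------------

    def signature(self, s: Iterable[int] | np.ndarray) -> MinHashSignature:
        """Raw minhash signature (t_1, ..., t_ell) of a nonempty set."""
        xs = np.asarray(sorted(s) if not isinstance(s, np.ndarray) else s, dtype=np.int64)
        if xs.size == 0:
            raise EmptySetError("minhash of an empty set is undefined")
        if xs.min() < 0 or xs.max() >= self.M:
            raise ValidationError(f"set element out of range [0, {self.M})")
        if self.mode == "explicit_permutation":
            values = self._perm_matrix()[:, xs].min(axis=1)
        else:
            a, b, p = self._universal_params()
            values = ((a[:, None] * xs[None, :] + b[:, None]) % p).min(axis=1)
        return MinHashSignature(values=values)

    def signatures(self, sets: Sequence[np.ndarray]) -> np.ndarray:
        """Signatures of many sets at once; returns an (n_sets, ell) array.

        Sets are padded with their own first element (min-invariant) so the
        per-permutation gather is a single fancy-indexing operation.
        """
        if not sets:
            return np.empty((0, self.ell), dtype=np.int64)
        arrs = [np.asarray(s, dtype=np.int64) for s in sets]
        for i, a in enumerate(arrs):
            if a.size == 0:
                raise EmptySetError(f"set {i} is empty; minhash undefined")
        max_len = max(a.size for a in arrs)
        padded = np.empty((len(arrs), max_len), dtype=np.int64)
        for i, a in enumerate(arrs):
            padded[i, : a.size] = a
            padded[i, a.size :] = a[0]
        if self.mode == "explicit_permutation":
            perms = self._perm_matrix()
            out = np.empty((len(arrs), self.ell), dtype=np.int64)
            for k in range(self.ell):
                out[:, k] = perms[k][padded].min(axis=1)
        else:
            a_, b_, p = self._universal_params()
            out = np.empty((len(arrs), self.ell), dtype=np.int64)
            for k in range(self.ell):
                out[:, k] = ((a_[k] * padded + b_[k]) % p).min(axis=1)
        return out

    def compact(self, s: Iterable[int] | np.ndarray) -> CompactFingerprint:
        """Compact fingerprint: additional-hashed signature bins."""
        sig = self.signature(s)
        bins = np.asarray(self.additional_hash(sig.values), dtype=np.int64)
        return CompactFingerprint(bins=bins, n_bins=self.N)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ell": self.ell,
            "M": self.M,
            "N": self.N,
            "master_seed": self.master_seed,
            "mode": self.mode,
            "identity_h": self.identity_h,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HashFamily":
        return cls(
            ell=int(d["ell"]),
            M=int(d["M"]),
            N=int(d["N"]),
            master_seed=int(d["master_seed"]),
            mode=str(d["mode"]),
            identity_h=bool(d.get("identity_h", False)),
        )


def make_hash_family(
    ell: int,
    M: int,
    N: int,
    master_seed: int,
    mode: str = "explicit_permutation",
    identity_h: bool = False,
) -> HashFamily:
    """Construct a reproducible family of ell permutations plus hash h."""
    return HashFamily(
        ell=ell, M=M, N=N, master_seed=master_seed, mode=mode, identity_h=identity_h
    )


def min_under_permutation(perm: np.ndarray, s: Iterable[int]) -> int:
    """min(perm(S)) for an explicit permutation image array.

    The elementary minhash step: ``perm[x]`` is the image of universe
    element x, and the sketch value of S is the smallest image over S.
    """
    perm = np.asarray(perm, dtype=np.int64)
    xs = np.asarray(sorted(set(int(x) for x in s)), dtype=np.int64)
    if xs.size == 0:
        raise EmptySetError("minhash of an empty set is undefined")
    if xs.min() < 0 or xs.max() >= perm.size:
        raise ValidationError(f"set element out of range [0, {perm.size})")
    return int(perm[xs].min())


def jaccard(s1: Iterable[int], s2: Iterable[int]) -> float:
    """|S1 n S2| / |S1 u S2|; undefined when both sets are empty."""
    a, b = set(s1), set(s2)
    if not a and not b:
        raise UndefinedSimilarityError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(a | b)


def minhash_value(s: Iterable[int], k: int, family: HashFamily) -> int:
    """t_k = min(pi_k(S)) for a nonempty set S."""
    xs = np.asarray(sorted(set(int(x) for x in s)), dtype=np.int64)
    if xs.size == 0:
        raise EmptySetError("minhash of an empty set is undefined")
    return int(family.apply_permutation(k, xs).min())


def additional_hash(t: int, family: HashFamily) -> int:
    """h(t) in [0, N); identical inputs always collide."""
    return int(family.additional_hash(int(t)))


def collision_probability(j: float, n: int) -> float:
    """Per-coordinate collision probability after additional hashing.

    ``1 - ((N-1)/N) * (1 - J)``: increasing in J, and approaching J as
    N grows (the pure-minhash limit).
    """
    if not 0.0 <= j <= 1.0:
        raise ValidationError(f"Jaccard similarity must be in [0, 1], got {j}")
    if n < 1:
        raise ValidationError(f"N must be >= 1, got {n}")
    return 1.0 - ((n - 1) / n) * (1.0 - j)


def compact_fingerprint(s: PairFeatureSet, family: HashFamily) -> CompactFingerprint:
    """Compact fingerprint of a pair's tensor feature set.

    Raises :class:`EmptySetError` naming the pair when the set is empty
    (a compound or protein with no active bits).
    """
    if len(s) == 0:
        raise EmptySetError(
            f"pair ({s.compound_id}, {s.protein_id}) has an empty feature set; "
            "minwise hashing is undefined",
            pair=(s.compound_id, s.protein_id),
        )
    return family.compact(s.members)


def encode_pairs(
    dataset: InteractionDataset,
    family: HashFamily,
    skip_empty: bool = False,
) -> tuple[sparse.csr_matrix, np.ndarray, list[tuple[str, str]], list[tuple[str, str]]]:
    """Encode every labeled pair of a dataset as a compact-fingerprint row.

    Returns ``(X, y, ids, skipped)`` where X is an (n_pairs, ell*N) CSR
    matrix with exactly ell ones per row.  Pairs with empty feature sets
    raise :class:`EmptySetError` unless ``skip_empty`` is set, in which
    case they are collected in ``skipped``.
    """
    sets, labels, ids, skipped = [], [], [], []
    for ps, (cid, pid, label) in zip(dataset.pair_sets(), dataset.pairs):
        if len(ps) == 0:
            if skip_empty:
                skipped.append((cid, pid))
                continue
            raise EmptySetError(
                f"pair ({cid}, {pid}) has an empty feature set; "
                "rerun with skip_empty to drop such pairs",
                pair=(cid, pid),
            )
        sets.append(ps.members)
        labels.append(label)
        ids.append((cid, pid))

    sigs = family.signatures(sets)
    bins = np.asarray(family.additional_hash(sigs), dtype=np.int64)
    n = len(sets)
    cols = (np.arange(family.ell, dtype=np.int64)[None, :] * family.N + bins).ravel()
    rows = np.repeat(np.arange(n, dtype=np.int64), family.ell)
    data = np.ones(n * family.ell, dtype=np.float64)
    x = sparse.csr_matrix(
        (data, (rows, cols)), shape=(n, family.ell * family.N)
    )
    return x, np.asarray(labels, dtype=np.int64), ids, skipped
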