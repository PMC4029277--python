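"""Binary fingerprints, tensor-product pair features, and their text I/O.

A compound is described by a D-dimensional binary substructure fingerprint
(presence/absence of predefined chemical substructures, e.g. the 881
PubChem bits) and a protein by a D'-dimensional binary domain fingerprint
(e.g. 4,137 PFAM domains).  A compound-protein pair is represented by the
tensor product of the two fingerprints: a D*D'-dimensional binary vector
whose active entries mark co-occurrence of a substructure with a domain.
We never materialize that vector densely; a pair is carried as the sorted
set of its active tensor indices.

All indices are 0-based half-open internally.  Literature presentations
that number features from 1 are a display convention only.

File formats (plain TSV, exactly round-tripping):

* fingerprint table::

      #dimension=<int>
      #dialect=bitstring|sparse
      <id>\t<payload>

  where payload is a 0/1 string of length ``dimension`` (bitstring) or a
  comma-separated list of active indices (sparse; empty payload = no bits).

* interaction table::

      #interactions
      <compound_id>\t<protein_id>\t<1|-1>
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ParseError, ValidationError

__all__ = [
    "BinaryFingerprint",
    "PairFeatureSet",
    "InteractionDataset",
    "tensor_index",
    "tensor_unindex",
    "pair_set",
    "read_fingerprint_table",
    "write_fingerprint_table",
    "read_interaction_table",
    "write_interaction_table",
]


@dataclass(frozen=True)
class BinaryFingerprint:
    """A sparse binary vector: the sorted set of active bit indices.

    Parameters
    ----------
    entity_id:
        Compound or protein identifier.
    dimension:
        Length of the underlying binary vector (D or D').
    active:
        Strictly increasing indices of the 1-bits, each in ``[0, dimension)``.
    """

    entity_id: str
    dimension: int
    active: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValidationError(
                f"fingerprint {self.entity_id!r}: dimension must be positive, "
                f"got {self.dimension}"
            )
        object.__setattr__(self, "active", tuple(int(a) for a in self.active))
        prev = -1
        for a in self.active:
            if a <= prev:
                raise ValidationError(
                    f"fingerprint {self.entity_id!r}: active indices must be "
                    f"strictly increasing and unique, got {self.active}"
                )
            if a >= self.dimension:
                raise ValidationError(
                    f"fingerprint {self.entity_id!r}: index {a} out of range "
                    f"for dimension {self.dimension}"
                )
            prev = a

    @classmethod
    def from_indices(
        cls, entity_id: str, dimension: int, indices: Iterable[int]
    ) -> "BinaryFingerprint":
        """Build from an unordered, possibly duplicated index collection."""
        return cls(entity_id, dimension, tuple(sorted(set(int(i) for i in indices))))

    @classmethod
    def from_bitstring(cls, entity_id: str, bits: str) -> "BinaryFingerprint":
        active = tuple(i for i, b in enumerate(bits) if b == "1")
        return cls(entity_id, len(bits), active)

    def to_bitstring(self) -> str:
        chars = ["0"] * self.dimension
        for a in self.active:
            chars[a] = "1"
        return "".join(chars)

    def __len__(self) -> int:
        return len(self.active)


def tensor_index(c: int, p: int, d_prime: int) -> int:
    """Compound-major flat index of tensor feature (c, p): ``c*D' + p``."""
    if d_prime <= 0:
        raise ValidationError(f"D' must be positive, got {d_prime}")
    if c < 0 or p < 0:
        raise ValidationError(f"feature indices must be nonnegative, got ({c}, {p})")
    if p >= d_prime:
        raise ValidationError(f"protein feature index {p} >= D'={d_prime}")
    return c * d_prime + p


def tensor_unindex(i: int, d_prime: int) -> tuple[int, int]:
    """Inverse of :func:`tensor_index`: ``i -> (i // D', i % D')``."""
    if d_prime <= 0:
        raise ValidationError(f"D' must be positive, got {d_prime}")
    if i < 0:
        raise ValidationError(f"tensor index must be nonnegative, got {i}")
    return divmod(i, d_prime)


@dataclass(frozen=True)
class PairFeatureSet:
    """The active tensor features of one compound-protein pair.

    ``members`` is the sorted set {c*D' + p : c active in the compound,
    p active in the protein}; its size is always the product of the two
    active-set sizes.
    """

    compound_id: str
    protein_id: str
    d: int
    d_prime: int
    members: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        members = np.asarray(self.members, dtype=np.int64)
        object.__setattr__(self, "members", members)
        if members.size and (members[0] < 0 or members[-1] >= self.d * self.d_prime):
            raise ValidationError(
                f"pair ({self.compound_id}, {self.protein_id}): tensor index "
                f"out of range [0, {self.d * self.d_prime})"
            )

    def __len__(self) -> int:
        return int(self.members.size)


def pair_set(compound: BinaryFingerprint, protein: BinaryFingerprint) -> PairFeatureSet:
    """Tensor-product feature set of a pair, built without densifying.

    Sorted because the compound indices are sorted and each compound bit
    contributes a contiguous block of D' candidates in protein order.
    """
    c = np.asarray(compound.active, dtype=np.int64)
    p = np.asarray(protein.active, dtype=np.int64)
    members = (c[:, None] * protein.dimension + p[None, :]).ravel()
    return PairFeatureSet(
        compound_id=compound.entity_id,
        protein_id=protein.entity_id,
        d=compound.dimension,
        d_prime=protein.dimension,
        members=members,
    )


@dataclass
class InteractionDataset:
    """Compound and protein fingerprints plus labeled interaction pairs."""

    compounds: dict[str, BinaryFingerprint]
    proteins: dict[str, BinaryFingerprint]
    pairs: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        dims_c = {f.dimension for f in self.compounds.values()}
        dims_p = {f.dimension for f in self.proteins.values()}
        if len(dims_c) > 1:
            raise ValidationError(f"compound fingerprints mix dimensions: {sorted(dims_c)}")
        if len(dims_p) > 1:
            raise ValidationError(f"protein fingerprints mix dimensions: {sorted(dims_p)}")
        seen: set[tuple[str, str]] = set()
        for cid, pid, label in self.pairs:
            if cid not in self.compounds:
                raise ValidationError(f"pair references unknown compound {cid!r}")
            if pid not in self.proteins:
                raise ValidationError(f"pair references unknown protein {pid!r}")
            if label not in (1, -1):
                raise ValidationError(f"pair ({cid}, {pid}): label must be +1/-1, got {label}")
            if (cid, pid) in seen:
                raise ValidationError(f"duplicate pair ({cid}, {pid})")
            seen.add((cid, pid))

    @property
    def d(self) -> int:
        return next(iter(self.compounds.values())).dimension

    @property
    def d_prime(self) -> int:
        return next(iter(self.proteins.values())).dimension

    def pair_sets(self) -> list[PairFeatureSet]:
        """Tensor feature sets for the labeled pairs, in pair order."""
        return [
            pair_set(self.compounds[cid], self.proteins[pid])
            for cid, pid, _ in self.pairs
        ]

    def labels(self) -> np.ndarray:
        return np.array([label for _, _, label in self.pairs], dtype=np.int64)


# ---------------------------------------------------------------------------
# Text I/O


def _parse_header(lines: list[str], path: str) -> tuple[int, str | None, int]:
    """Returns (dimension, declared dialect or None, first data line index)."""
    dimension = None
    dialect = None
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition("=")
        if key.strip() == "dimension":
            try:
                dimension = int(value)
            except ValueError as exc:
                raise ParseError(f"{path}: bad dimension {value!r}", i + 1) from exc
        elif key.strip() == "dialect":
            dialect = value.strip()
            if dialect not in ("bitstring", "sparse"):
                raise ParseError(f"{path}: unknown dialect {dialect!r}", i + 1)
        i += 1
    if dimension is None:
        raise ParseError(f"{path}: missing '#dimension=<int>' header")
    return dimension, dialect, i


def read_fingerprint_table(
    path: str | Path, dialect: str | None = None
) -> dict[str, BinaryFingerprint]:
    """Read a fingerprint TSV into an id -> fingerprint mapping.

    The header declares the dimension and (optionally) the dialect; a
    ``dialect`` argument overrides auto-detection from the header.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    dimension, header_dialect, start = _parse_header(lines, str(path))
    dialect = dialect or header_dialect
    if dialect is None:
        raise ParseError(f"{path}: dialect not declared and not given")

    out: dict[str, BinaryFingerprint] = {}
    for lineno0, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}: expected 'id<TAB>payload', got {len(parts)} fields", lineno0
            )
        entity_id, payload = parts
        if entity_id in out:
            raise ValidationError(f"{path}: duplicate id {entity_id!r} at line {lineno0}")
        if dialect == "bitstring":
            if len(payload) != dimension or set(payload) - {"0", "1"}:
                raise ParseError(
                    f"{path}: payload must be a 0/1 string of length {dimension}", lineno0
                )
            fp = BinaryFingerprint.from_bitstring(entity_id, payload)
        else:
            try:
                indices = [int(tok) for tok in payload.split(",") if tok.strip() != ""]
            except ValueError as exc:
                raise ParseError(f"{path}: bad sparse payload {payload!r}", lineno0) from exc
            fp = BinaryFingerprint.from_indices(entity_id, dimension, indices)
        out[entity_id] = fp
    return out


def write_fingerprint_table(
    path: str | Path,
    fingerprints: Iterable[BinaryFingerprint],
    dialect: str = "sparse",
) -> None:
    if dialect not in ("bitstring", "sparse"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    fps = list(fingerprints)
    if not fps:
        raise ValidationError("cannot write an empty fingerprint table")
    dimension = fps[0].dimension
    lines = [f"#dimension={dimension}", f"#dialect={dialect}"]
    for fp in fps:
        if fp.dimension != dimension:
            raise ValidationError("all fingerprints in one table must share a dimension")
        payload = (
            fp.to_bitstring()
            if dialect == "bitstring"
            else ",".join(str(a) for a in fp.active)
        )
        lines.append(f"{fp.entity_id}\t{payload}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_interaction_table(path: str | Path) -> list[tuple[str, str, int]]:
    path = Path(path)
    lines = path.read_text().splitlines()
    pairs: list[tuple[str, str, int]] = []
    for lineno0, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"{path}: expected 'compound<TAB>protein<TAB>label'", lineno0
            )
        cid, pid, label_s = parts
        try:
            label = int(label_s)
        except ValueError as exc:
            raise ParseError(f"{path}: bad label {label_s!r}", lineno0) from exc
        if label not in (1, -1):
            raise ParseError(f"{path}: label must be 1 or -1, got {label}", lineno0)
        pairs.append((cid, pid, label))
    return pairs


def write_interaction_table(
    path: str | Path, pairs: Sequence[tuple[str, str, int]]
) -> None:
    lines = ["#interactions"]
    for cid, pid, label in pairs:
        lines.append(f"{cid}\t{pid}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")


def encode_direct(
    dataset: InteractionDataset,
) -> tuple["object", np.ndarray, list[tuple[str, str]]]:
    """Encode labeled pairs as sparse rows over the raw D*D' tensor features.

    This is the uncompressed route the compact fingerprints approximate;
    feasible only at desk scale.  Returns ``(X, y, ids)`` with X a CSR
    matrix of shape (n_pairs, D*D').
    """
    from scipy import sparse  # local import keeps the base module light

    d_total = dataset.d * dataset.d_prime
    sets = dataset.pair_sets()
    indptr = np.zeros(len(sets) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(s) for s in sets])
    indices = (
        np.concatenate([s.members for s in sets])
        if sets
        else np.empty(0, dtype=np.int64)
    )
    data = np.ones(indices.size, dtype=np.float64)
    x = sparse.csr_matrix((data, indices, indptr), shape=(len(sets), d_total))
    ids = [(cid, pid) for cid, pid, _ in dataset.pairs]
    return x, dataset.labels(), ids


def load_dataset(
    compound_path: str | Path,
    protein_path: str | Path,
    interaction_path: str | Path,
) -> InteractionDataset:
    """Load the three tables of one dataset and validate cross-references."""
    return InteractionDataset(
        compounds=read_fingerprint_table(compound_path),
        proteins=read_fingerprint_table(protein_path),
        pairs=read_interaction_table(interaction_path),
    )
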