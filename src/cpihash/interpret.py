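"""Recover tensor-feature weights from a compact-fingerprint model.

A weight learned on compact-fingerprint coordinate ``k*N + b`` speaks
about every original tensor feature whose k-th minhash image hashes to
bin b.  Inverting the chain (h then pi_k, h being one-to-many) and
averaging the contributions over the ell blocks yields a weight estimate
on the original substructure x domain features:

    recovered[i] = (1/ell) * sum_k  w[k*N + h(pi_k(i))]

The forward composition above visits, for each block k, exactly the one
bin that feature i lands in, so it equals the explicit inverse-mapping
procedure (enumerate the h-preimage of each bin, pull each element back
through pi_k^-1) without ever materializing the one-to-many tables.

Ranked substructure-domain associations are the interpretable output:
each recovered index decomposes as (compound substructure, protein
domain) via the tensor layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ModeError, ValidationError
from .fingerprints import InteractionDataset, tensor_unindex
from .model import LinearModel

__all__ = ["RecoveredWeights", "recover_weights", "top_features", "write_features_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class RecoveredWeights:
    """Sparse map from tensor feature index to recovered weight."""

    indices: np.ndarray
    values: np.ndarray
    d: int
    d_prime: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.indices.size != self.values.size:
            raise ValidationError("indices and values must have equal length")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.d * self.d_prime
        ):
            raise ValidationError(f"tensor index out of range [0, {self.d * self.d_prime})")

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(v) for i, v in zip(self.indices, self.values)}

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.values))


def _observed_indices(dataset: InteractionDataset) -> np.ndarray:
    members = [ps.members for ps in dataset.pair_sets() if len(ps)]
    if not members:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(members))


def recover_weights(
    model: LinearModel,
    d: int,
    d_prime: int,
    restrict_to: np.ndarray | None = None,
    dataset: InteractionDataset | None = None,
    all_features: bool = False,
    chunk_size: int = 1 << 18,
) -> RecoveredWeights:
    """Average compact-fingerprint weights back onto tensor features.

    The recovery domain is, in order of precedence: ``restrict_to``, the
    tensor features observed in ``dataset``'s pair sets, or (with
    ``all_features``) the full [0, D*D') range.  Enumerating the full
    range is exact but wasteful for large universes, hence the default of
    restricting to observed features.
    """
    if model.mode != "compact":
        raise ModeError(
            "direct-mode weights already live in tensor coordinates; "
            "recovery applies to compact-mode models only"
        )
    family = model.family
    assert family is not None  # guaranteed by LinearModel validation
    if family.M != d * d_prime:
        raise ValidationError(
            f"family universe M={family.M} does not match D*D'={d * d_prime}"
        )
    if restrict_to is not None:
        indices = np.unique(np.asarray(restrict_to, dtype=np.int64))
    elif all_features:
        indices = np.arange(d * d_prime, dtype=np.int64)
    elif dataset is not None:
        indices = _observed_indices(dataset)
    else:
        raise ValidationError(
            "provide restrict_to, a dataset, or all_features=True to define "
            "the recovery domain"
        )
    values = np.zeros(indices.size, dtype=np.float64)
    for start in range(0, indices.size, chunk_size):
        chunk = indices[start : start + chunk_size]
        acc = np.zeros(chunk.size, dtype=np.float64)
        for k in range(family.ell):
            t = family.apply_permutation(k, chunk)
            bins = np.asarray(family.additional_hash(t), dtype=np.int64)
            acc += model.weights[k * family.N + bins]
        values[start : start + chunk_size] = acc / family.ell
    return RecoveredWeights(indices=indices, values=values, d=d, d_prime=d_prime)


def top_features(
    recovered: RecoveredWeights,
    k: int,
    compound_labels: dict[int, str] | None = None,
    protein_labels: dict[int, str] | None = None,
) -> list[tuple[int, int, float]]:
    """The k highest-weight (substructure, domain, weight) associations.

    Sorted by descending weight; ties broken by ascending tensor index so
    the ranking is deterministic.  Optional label maps annotate entries in
    :func:`write_features_tsv`; here only raw indices are returned.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > recovered.indices.size:
        logger.warning(
            "requested top %d features but only %d recovered entries exist",
            k,
            recovered.indices.size,
        )
        k = recovered.indices.size
    order = np.lexsort((recovered.indices, -recovered.values))[:k]
    _ = (compound_labels, protein_labels)
    return [
        (*tensor_unindex(int(recovered.indices[i]), recovered.d_prime), float(recovered.values[i]))
        for i in order
    ]


def write_features_tsv(
    recovered: RecoveredWeights,
    path: str | Path,
    k: int | None = None,
    compound_labels: dict[int, str] | None = None,
    protein_labels: dict[int, str] | None = None,
) -> None:
    """Write ranked substructure-domain associations as TSV."""
    k = recovered.indices.size if k is None else min(k, recovered.indices.size)
    rows = top_features(recovered, max(k, 1)) if k else []
    with_labels = compound_labels is not None or protein_labels is not None
    header = ["substructure_index", "domain_index"]
    if with_labels:
        header += ["substructure_label", "domain_label"]
    header.append("weight")
    lines = ["\t".join(header)]
    for c, p, w in rows:
        fields = [str(c), str(p)]
        if with_labels:
            fields.append((compound_labels or {}).get(c, ""))
            fields.append((protein_labels or {}).get(p, ""))
        fields.append(f"{w:.12g}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
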