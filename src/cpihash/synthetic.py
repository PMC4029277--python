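"""Synthetic interaction data with a planted sparse tensor-feature model.

The generator emulates the statistical shape of chemogenomic screening
data: sparse binary substructure fingerprints for compounds, sparse
binary domain fingerprints for proteins, and interaction labels driven by
a small number of substructure-domain co-occurrence features — exactly
the hypothesis class of the tensor-product linear classifier, so that
recovery of the planted weights is a meaningful end-to-end check.

Generation steps, all deterministic given the seed:

1. Fingerprint bits are i.i.d. Bernoulli at the configured densities;
   an entity drawing no bits at all is redrawn, since a compound with no
   substructure (or a protein with no domain) carries no signal and real
   curated fingerprints are nonempty.
2. ``n_planted`` tensor indices get weights of magnitude ``effect_scale``
   with random sign; a pair's raw score sums the planted weights on its
   active tensor features.
3. Pairs are ranked by raw score (seeded jitter breaks ties) and the top
   block is labeled +1.  The block size is chosen so that after symmetric
   label flipping at rate ``label_noise`` the *expected* positive
   fraction equals ``positive_fraction_target``.

The generator does not model substructure co-occurrence structure or
domain grammar; it is a statistical stand-in for real screening data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import GenerationError, ValidationError
from .fingerprints import (
    BinaryFingerprint,
    InteractionDataset,
    write_fingerprint_table,
    write_interaction_table,
)

__all__ = ["SyntheticConfig", "SyntheticResult", "generate_synthetic_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the planted-model generator (desk-scale defaults)."""

    n_compounds: int = 100
    n_proteins: int = 80
    d: int = 50
    d_prime: int = 40
    compound_density: float = 0.15
    protein_density: float = 0.12
    n_planted: int = 40
    effect_scale: float = 1.0
    label_noise: float = 0.02
    positive_fraction_target: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_proteins < 1:
            raise ValidationError("need at least one compound and one protein")
        if self.d < 1 or self.d_prime < 1:
            raise ValidationError("fingerprint dimensions must be positive")
        for name, density in (
            ("compound_density", self.compound_density),
            ("protein_density", self.protein_density),
        ):
            if not 0.0 < density < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {density}")
        if not 1 <= self.n_planted <= self.d * self.d_prime:
            raise ValidationError(
                f"n_planted must lie in [1, {self.d * self.d_prime}], got {self.n_planted}"
            )
        if self.effect_scale <= 0:
            raise ValidationError(f"effect_scale must be positive, got {self.effect_scale}")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValidationError(f"label_noise must lie in [0, 0.5), got {self.label_noise}")
        if not 0.0 < self.positive_fraction_target < 1.0:
            raise ValidationError(
                f"positive_fraction_target must lie in (0, 1), got "
                f"{self.positive_fraction_target}"
            )


@dataclass
class SyntheticResult:
    """A generated dataset plus the ground truth used to label it."""

    dataset: InteractionDataset
    planted: dict[int, float]
    scores: np.ndarray = field(repr=False)  # (n_compounds, n_proteins) raw scores
    threshold: float = 0.0

    def write(self, directory: str | Path, dialect: str = "sparse") -> dict[str, Path]:
        """Write the three dataset tables plus the planted weights."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": directory / "compounds.tsv",
            "proteins": directory / "proteins.tsv",
            "interactions": directory / "interactions.tsv",
            "planted": directory / "planted.tsv",
        }
        write_fingerprint_table(
            paths["compounds"], self.dataset.compounds.values(), dialect
        )
        write_fingerprint_table(
            paths["proteins"], self.dataset.proteins.values(), dialect
        )
        write_interaction_table(paths["interactions"], self.dataset.pairs)
        lines = ["#tensor_index\tweight"] + [
            f"{i}\t{w:.12g}" for i, w in sorted(self.planted.items())
        ]
        paths["planted"].write_text("\n".join(lines) + "\n")
        return paths


def _random_fingerprints(
    rng: np.random.Generator,
    prefix: str,
    count: int,
    dimension: int,
    density: float,
) -> dict[str, BinaryFingerprint]:
    width = len(str(count - 1))
    out: dict[str, BinaryFingerprint] = {}
    for i in range(count):
        active = np.nonzero(rng.random(dimension) < density)[0]
        while active.size == 0:  # nonempty by construction; see module docstring
            active = np.nonzero(rng.random(dimension) < density)[0]
        entity_id = f"{prefix}{i:0{width}d}"
        out[entity_id] = BinaryFingerprint(entity_id, dimension, tuple(active))
    return out


def generate_synthetic_dataset(config: SyntheticConfig) -> SyntheticResult:
    """Generate fingerprints, planted weights, and noisy labels.

    The pre-noise positive count is ``n * (target - noise) / (1 - 2*noise)``
    so that the expected labeled-positive fraction after symmetric label
    flipping equals ``positive_fraction_target``; this requires
    ``label_noise < positive_fraction_target``.
    """
    rng = np.random.default_rng(config.seed)
    compounds = _random_fingerprints(
        rng, "c", config.n_compounds, config.d, config.compound_density
    )
    proteins = _random_fingerprints(
        rng, "p", config.n_proteins, config.d_prime, config.protein_density
    )

    planted_idx = np.sort(
        rng.choice(config.d * config.d_prime, size=config.n_planted, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=config.n_planted)
    planted = {int(i): float(s * config.effect_scale) for i, s in zip(planted_idx, signs)}

    c_ids = list(compounds)
    p_ids = list(proteins)
    c_bits = np.zeros((config.n_compounds, config.d), dtype=np.float64)
    for i, cid in enumerate(c_ids):
        c_bits[i, list(compounds[cid].active)] = 1.0
    p_bits = np.zeros((config.n_proteins, config.d_prime), dtype=np.float64)
    for j, pid in enumerate(p_ids):
        p_bits[j, list(proteins[pid].active)] = 1.0

    scores = np.zeros((config.n_compounds, config.n_proteins))
    for idx, weight in planted.items():
        c_feat, p_feat = divmod(idx, config.d_prime)
        scores += weight * np.outer(c_bits[:, c_feat], p_bits[:, p_feat])

    flat = scores.ravel()
    if np.ptp(flat) == 0.0:
        raise GenerationError(
            "all pair scores are identical; no labeling threshold exists — "
            "increase densities, n_planted, or effect_scale"
        )
    n = flat.size
    target, noise = config.positive_fraction_target, config.label_noise
    if target <= noise:
        raise GenerationError(
            f"positive_fraction_target ({target}) must exceed label_noise "
            f"({noise}) for the post-noise fraction to be achievable"
        )
    n_pos = int(round(n * (target - noise) / (1.0 - 2.0 * noise)))
    if not 0 < n_pos < n:
        raise GenerationError(
            f"pre-noise positive count {n_pos} is degenerate for n={n}"
        )
    jitter = rng.permutation(n)  # deterministic tie-break among equal scores
    order = np.lexsort((jitter, -flat))
    labels = np.full(n, -1, dtype=np.int64)
    labels[order[:n_pos]] = 1
    threshold = float(flat[order[n_pos - 1]])
    if config.label_noise > 0.0:
        flips = rng.random(n) < config.label_noise
        labels[flips] *= -1

    pairs = [
        (c_ids[i], p_ids[j], int(labels[i * config.n_proteins + j]))
        for i in range(config.n_compounds)
        for j in range(config.n_proteins)
    ]
    dataset = InteractionDataset(compounds=compounds, proteins=proteins, pairs=pairs)
    return SyntheticResult(
        dataset=dataset, planted=planted, scores=scores, threshold=threshold
    )
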