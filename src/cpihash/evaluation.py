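"""Cross-validation protocols, negative sampling, and AUC scoring.

Two 5-fold protocols mirror the two prediction scenarios:

* pair-wise CV splits the labeled compound-protein *pairs* into folds —
  the "fill in missing interactions among known entities" scenario;
* block-wise CV splits the *compounds* into folds and the *proteins*
  into folds; test fold i is the block (compound fold i x protein fold
  i), and training uses only pairs whose compound AND protein lie in the
  remaining folds — the cold-start scenario for entirely new entities.
  Pairs straddling a test entity and a train entity are used in neither.

Negative examples are sampled uniformly without replacement from the
non-positive cells of the compound x protein grid at a chosen
positive:negative ratio (unlabeled pairs are treated as negatives, the
usual assumption when the gold standard lists only interactions).

AUC is the Mann-Whitney statistic with midrank tie handling,
P(s+ > s-) + 0.5 * P(s+ = s-), identical to the trapezoidal area under
the empirical ROC curve.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateProblemError, UndefinedAUCError, ValidationError
from .fingerprints import InteractionDataset, encode_direct
from .minhash import HashFamily, encode_pairs, make_hash_family
from .model import TrainingDesign, decision_scores, train_linear_svm

__all__ = [
    "FoldAssignment",
    "pairwise_cv_split",
    "blockwise_cv_split",
    "sample_negatives",
    "subsample_dataset",
    "auc_score",
    "ExperimentConfig",
    "CVResult",
    "run_cv_experiment",
]

logger = logging.getLogger(__name__)

FULL_C_GRID = tuple(10.0**e for e in range(-5, 6))


@dataclass
class FoldAssignment:
    """Fold memberships for one CV scheme.

    Pairwise: ``test_folds[i]`` holds the pair indices of test fold i.
    Blockwise: ``compound_folds`` / ``protein_folds`` map entity ids to
    fold numbers; pair memberships are derived per fold.
    """

    scheme: str
    n_folds: int
    seed: int
    test_folds: list[np.ndarray] = field(default_factory=list)
    compound_folds: dict[str, int] = field(default_factory=dict)
    protein_folds: dict[str, int] = field(default_factory=dict)

    def train_test_indices(
        self,
        pairs: Sequence[tuple[str, str, int]],
        fold: int,
        protein_fold: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pair-index arrays (train, test) for one fold of this assignment.

        Blockwise folds pair compound fold ``fold`` with protein fold
        ``protein_fold`` (default: the same number, the diagonal pairing);
        passing every (fold, protein_fold) combination yields the full
        grid of held-out blocks.
        """
        if not 0 <= fold < self.n_folds:
            raise ValidationError(f"fold {fold} out of range [0, {self.n_folds})")
        if self.scheme == "pairwise":
            if protein_fold is not None:
                raise ValidationError("protein_fold applies to blockwise folds only")
            test = self.test_folds[fold]
            mask = np.ones(len(pairs), dtype=bool)
            mask[test] = False
            return np.nonzero(mask)[0], test
        p_fold = fold if protein_fold is None else protein_fold
        if not 0 <= p_fold < self.n_folds:
            raise ValidationError(f"protein fold {p_fold} out of range [0, {self.n_folds})")
        train_idx, test_idx = [], []
        for i, (cid, pid, _) in enumerate(pairs):
            cf, pf = self.compound_folds[cid], self.protein_folds[pid]
            if cf == fold and pf == p_fold:
                test_idx.append(i)
            elif cf != fold and pf != p_fold:
                train_idx.append(i)
        return np.asarray(train_idx, dtype=np.int64), np.asarray(test_idx, dtype=np.int64)


def _partition(indices: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle and split into folds of near-equal size (max-min <= 1).

    Remainder elements go to the lowest-numbered folds.
    """
    shuffled = rng.permutation(indices)
    base, rem = divmod(indices.size, n_folds)
    folds, start = [], 0
    for i in range(n_folds):
        size = base + (1 if i < rem else 0)
        folds.append(np.sort(shuffled[start : start + size]))
        start += size
    return folds


def pairwise_cv_split(
    pairs: Sequence[tuple[str, str, int]],
    n_folds: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> FoldAssignment:
    """Random partition of pairs into test folds of near-equal size."""
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    if len(pairs) < n_folds:
        raise ValidationError(f"{len(pairs)} pairs cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    if stratified:
        labels = np.array([label for _, _, label in pairs])
        pos_folds = _partition(np.nonzero(labels == 1)[0], n_folds, rng)
        neg_folds = _partition(np.nonzero(labels == -1)[0], n_folds, rng)
        test_folds = [
            np.sort(np.concatenate([p, n])) for p, n in zip(pos_folds, neg_folds)
        ]
    else:
        test_folds = _partition(np.arange(len(pairs)), n_folds, rng)
    return FoldAssignment(
        scheme="pairwise", n_folds=n_folds, seed=seed, test_folds=test_folds
    )


def blockwise_cv_split(
    compound_ids: Sequence[str],
    protein_ids: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Partition compounds and proteins separately into folds.

    Test fold i pairs compound fold i with protein fold i (the diagonal
    pairing; a full grid of fold combinations is a caller-side loop over
    reassigned fold labels if wanted).
    """
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    if len(compound_ids) < n_folds or len(protein_ids) < n_folds:
        raise ValidationError("need at least n_folds compounds and proteins")
    rng = np.random.default_rng(seed)
    compound_ids = list(compound_ids)
    protein_ids = list(protein_ids)
    c_folds = _partition(np.arange(len(compound_ids)), n_folds, rng)
    p_folds = _partition(np.arange(len(protein_ids)), n_folds, rng)
    compound_map = {compound_ids[i]: f for f, idx in enumerate(c_folds) for i in idx}
    protein_map = {protein_ids[i]: f for f, idx in enumerate(p_folds) for i in idx}
    return FoldAssignment(
        scheme="blockwise",
        n_folds=n_folds,
        seed=seed,
        compound_folds=compound_map,
        protein_folds=protein_map,
    )


def sample_negatives(
    positives: set[tuple[str, str]],
    compound_ids: Sequence[str],
    protein_ids: Sequence[str],
    ratio: float,
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Uniform sample of non-positive grid cells, labeled -1.

    ``ratio`` is negatives per positive; ``math.inf`` requests every
    non-positive pair.
    """
    compound_ids = list(compound_ids)
    protein_ids = list(protein_ids)
    n_total = len(compound_ids) * len(protein_ids)
    n_available = n_total - len(positives)
    if math.isinf(ratio):
        n_neg = n_available
    else:
        if ratio <= 0:
            raise ValidationError(f"ratio must be positive, got {ratio}")
        n_neg = round(ratio * len(positives))
        if n_neg > n_available:
            raise ValidationError(
                f"ratio {ratio} needs {n_neg} negatives but only {n_available} "
                f"non-positive pairs exist (max feasible ratio: "
                f"{n_available / max(len(positives), 1):.3f})"
            )
    c_index = {c: i for i, c in enumerate(compound_ids)}
    p_index = {p: i for i, p in enumerate(protein_ids)}
    for c, p in positives:
        if c not in c_index or p not in p_index:
            raise ValidationError(f"positive pair ({c}, {p}) references unknown entities")
    pos_flat = {c_index[c] * len(protein_ids) + p_index[p] for c, p in positives}
    rng = np.random.default_rng(seed)
    if n_total <= 5_000_000:
        pool = np.setdiff1d(
            np.arange(n_total, dtype=np.int64),
            np.fromiter(pos_flat, dtype=np.int64, count=len(pos_flat)),
            assume_unique=True,
        )
        chosen = pool if n_neg == pool.size else rng.choice(pool, size=n_neg, replace=False)
        chosen = np.sort(chosen)
    else:  # rejection sampling for grids too large to enumerate
        chosen_set: set[int] = set()
        while len(chosen_set) < n_neg:
            draws = rng.integers(0, n_total, size=2 * (n_neg - len(chosen_set)))
            for flat in draws:
                flat = int(flat)
                if flat not in pos_flat and flat not in chosen_set:
                    chosen_set.add(flat)
                    if len(chosen_set) == n_neg:
                        break
        chosen = np.sort(np.fromiter(chosen_set, dtype=np.int64, count=n_neg))
    n_p = len(protein_ids)
    return [(compound_ids[f // n_p], protein_ids[f % n_p], -1) for f in chosen]


def subsample_dataset(
    dataset: InteractionDataset, ratio: float, seed: int = 0
) -> InteractionDataset:
    """Keep all positive pairs and a seeded sample of labeled negatives.

    Emulates the ratio experiments: the gold-standard positives plus
    ``ratio`` times as many negatives drawn from the labeled -1 pairs.
    """
    positives = [pr for pr in dataset.pairs if pr[2] == 1]
    negatives = [pr for pr in dataset.pairs if pr[2] == -1]
    if math.isinf(ratio):
        chosen = negatives
    else:
        n_neg = round(ratio * len(positives))
        if n_neg > len(negatives):
            raise ValidationError(
                f"ratio {ratio} needs {n_neg} negatives, only {len(negatives)} labeled"
            )
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(negatives), size=n_neg, replace=False))
        chosen = [negatives[i] for i in idx]
    return InteractionDataset(
        compounds=dataset.compounds,
        proteins=dataset.proteins,
        pairs=positives + chosen,
    )


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with midrank ties: P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs both a positive and a negative example")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class ExperimentConfig:
    """Settings for one cross-validated training/evaluation run.

    ``n_bins`` is capped at the universe size M, matching the sweep regime
    where N is never allowed to exceed the number of hashable values.
    """

    mode: str = "compact"  # 'compact' (MH-) or 'direct'
    regularization: str = "l2"
    c_grid: Sequence[float] = (1.0,)
    ell: int = 10
    n_bins: int = 2**16
    n_folds: int = 5
    stratified: bool = False
    fit_bias: bool = False
    tolerance: float = 1e-3
    max_iterations: int = 1000
    skip_empty: bool = False
    hash_mode: str | None = None  # None: explicit if M fits, else universal

    def __post_init__(self) -> None:
        if self.mode not in ("compact", "direct"):
            raise ValidationError(f"mode must be 'compact' or 'direct', got {self.mode!r}")
        if not self.c_grid:
            raise ValidationError("c_grid must contain at least one C value")


@dataclass
class CVResult:
    """Per-fold AUC table plus the best-C summary of one CV run."""

    scheme: str
    table: pd.DataFrame  # columns: fold, C, auc
    best_c: float
    fold_aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    seconds: float
    family: HashFamily | None = None

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "best_C": self.best_c,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "seconds": self.seconds,
        }


def _derive_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def run_cv_experiment(
    dataset: InteractionDataset,
    config: ExperimentConfig,
    scheme: str = "pairwise",
    seed: int = 0,
) -> CVResult:
    """Encode, split, train, and score one dataset under one protocol.

    The hyper-parameter C is swept over ``config.c_grid`` and chosen as
    the value with the best mean test-fold AUC (the protocol's selection
    rule; use a nested split upstream if an unbiased estimate is needed).
    All randomness (hash family, fold split, solver) derives from ``seed``.
    """
    t0 = time.perf_counter()
    if scheme not in ("pairwise", "blockwise"):
        raise ValidationError(f"scheme must be 'pairwise' or 'blockwise', got {scheme!r}")
    m = dataset.d * dataset.d_prime
    family: HashFamily | None = None
    if config.mode == "compact":
        n_bins = min(config.n_bins, m)
        hash_mode = config.hash_mode or (
            "explicit_permutation" if m <= (1 << 24) else "universal_hash"
        )
        family = make_hash_family(
            ell=config.ell,
            M=m,
            N=n_bins,
            master_seed=_derive_seed(seed, 1),
            mode=hash_mode,
        )
        x, y, ids, skipped = encode_pairs(dataset, family, skip_empty=config.skip_empty)
        if skipped:
            logger.warning("dropped %d pairs with empty feature sets", len(skipped))
        pairs = [(c, p, int(lbl)) for (c, p), lbl in zip(ids, y)]
    else:
        x, y, ids = encode_direct(dataset)
        pairs = list(dataset.pairs)

    if scheme == "pairwise":
        assignment = pairwise_cv_split(
            pairs, config.n_folds, seed=_derive_seed(seed, 2), stratified=config.stratified
        )
    else:
        assignment = blockwise_cv_split(
            sorted(dataset.compounds),
            sorted(dataset.proteins),
            config.n_folds,
            seed=_derive_seed(seed, 2),
        )

    records = []
    for fold in range(config.n_folds):
        train_idx, test_idx = assignment.train_test_indices(pairs, fold)
        design = TrainingDesign(
            x=x[train_idx], y=y[train_idx], ids=[ids[i] for i in train_idx]
        )
        for c_value in config.c_grid:
            try:
                model = train_linear_svm(
                    design,
                    regularization=config.regularization,
                    C=c_value,
                    tolerance=config.tolerance,
                    max_iterations=config.max_iterations,
                    seed=_derive_seed(seed, 3),
                    mode=config.mode,
                    family=family,
                )
                auc = auc_score(decision_scores(model, x[test_idx]), y[test_idx])
            except (DegenerateProblemError, UndefinedAUCError) as exc:
                logger.warning("fold %d, C=%g: %s", fold, c_value, exc)
                auc = float("nan")
            records.append({"fold": fold, "C": c_value, "auc": auc})

    table = pd.DataFrame.from_records(records)
    mean_by_c = table.groupby("C")["auc"].mean()
    best_c = float(mean_by_c.idxmax())
    fold_aucs = (
        table[table["C"] == best_c].sort_values("fold")["auc"].to_numpy()
    )
    return CVResult(
        scheme=scheme,
        table=table,
        best_c=best_c,
        fold_aucs=fold_aucs,
        mean_auc=float(np.nanmean(fold_aucs)),
        sd_auc=float(np.nanstd(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        seconds=time.perf_counter() - t0,
        family=family,
    )
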