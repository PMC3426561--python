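"""K-fold partitioning, architecture search, and voting ensembles.

Each fold of a K-fold plan serves once as the held-out test set; the
remaining examples are split into training and validation subsets (the
validation fraction is itself a tuned quantity). Fold-level test accuracy
uses the same sign rule as ensembles: an output > 0 is a positive call,
<= 0 a negative one. The K trained networks are then ranked by held-out
accuracy and the top N vote by averaging their outputs.

All randomness flows from one master seed through :func:`derive_seed`, a
documented stable hash of (master, stage tags), so an entire grid search is
reproducible from a single integer.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import LabeledDataset
from .neuralnet import MLPModel, TrainingConfig, init_model, train


def derive_seed(master: int, *tags) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed and tags."""
    text = ":".join([str(master), *map(str, tags)])
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint balanced partition of ``n`` indices into ``k`` folds."""

    n: int
    k: int
    fold_assignments: np.ndarray  # (n,) fold id per index
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_assignments, minlength=self.k)


def make_folds(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Seeded uniform random partition with fold sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    # first (n mod k) folds get the extra example
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignments[order[start: start + size]] = fold
        start += size
    return FoldPlan(n=n, k=k, fold_assignments=assignments, seed=seed)


def split_train_validation(
    indices: np.ndarray, val_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint train/validation split; |validation| = round(f * n)."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    indices = np.asarray(indices)
    n_val = round(val_fraction * indices.size)
    if n_val == 0 or n_val == indices.size:
        raise ValueError(f"split of {indices.size} at {val_fraction} leaves one side empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(indices.size)
    return indices[order[n_val:]], indices[order[:n_val]]


def sign_decision(outputs: np.ndarray) -> np.ndarray:
    """+1 where output > 0, else -1 (zero counts as a negative call)."""
    return np.where(np.asarray(outputs) > 0, 1, -1)


@dataclass
class FoldResult:
    """One cross-validation member: its model and held-out performance."""

    fold: int
    model: MLPModel
    accuracy: float
    test_indices: np.ndarray
    test_outputs: np.ndarray
    test_labels: np.ndarray


def crossval_train(
    dataset: LabeledDataset,
    hidden_layers: Sequence[int],
    val_fraction: float = 0.2,
    k: int = 10,
    config: Optional[TrainingConfig] = None,
    seed: int = 0,
) -> list[FoldResult]:
    """Train one network per fold; accuracy is sign-correct rate on the fold.

    Architecture is given as hidden layer sizes, e.g. ``[40]`` or
    ``[90, 10]``; the input width comes from the dataset and the output is
    one unit. Fully seeded: folds, splits, and weight init all derive from
    ``seed``.
    """
    config = config or TrainingConfig()
    plan = make_folds(len(dataset), k, derive_seed(seed, "folds", k))
    sizes = [dataset.n_features, *hidden_layers, 1]
    results = []
    for fold in range(k):
        test_idx = plan.fold_indices(fold)
        rest = np.flatnonzero(plan.fold_assignments != fold)
        tr_idx, va_idx = split_train_validation(
            rest, val_fraction, derive_seed(seed, "split", fold)
        )
        model = init_model(
            sizes,
            dataset.X[tr_idx],
            seed=derive_seed(seed, "init", fold),
            config=config,
            meta={"fold": fold, "include_pi": dataset.include_pi},
        )
        model, _ = train(
            model, dataset.X[tr_idx], dataset.y[tr_idx], dataset.X[va_idx], dataset.y[va_idx], config
        )
        labels = dataset.y[test_idx]
        if len(set(labels.tolist())) < 2:
            warnings.warn(f"fold {fold} holds a single class; accuracy still defined", stacklevel=2)
        outputs = model.forward(dataset.X[test_idx])
        accuracy = float(np.mean(sign_decision(outputs) == labels))
        results.append(
            FoldResult(
                fold=fold,
                model=model,
                accuracy=accuracy,
                test_indices=test_idx,
                test_outputs=outputs,
                test_labels=labels,
            )
        )
    return results


def grid_search(
    dataset: LabeledDataset,
    architectures: Sequence[Sequence[int]],
    val_fractions: Sequence[float],
    k: int = 10,
    config: Optional[TrainingConfig] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full-factorial architecture x validation-split search.

    Returns a long-format table (architecture, val_fraction, mean/std
    accuracy) and the argmax cell; ties resolve to the smaller network
    (fewer total hidden units), then fewer layers, then the smaller
    validation fraction.
    """
    if not architectures or not val_fractions:
        raise ValueError("grids must be non-empty")
    rows = []
    for arch in architectures:
        arch = tuple(arch)
        for vf in val_fractions:
            results = crossval_train(dataset, arch, vf, k, config, seed=derive_seed(seed, "grid", arch, vf))
            accs = np.array([r.accuracy for r in results])
            rows.append(
                {
                    "architecture": "x".join(map(str, arch)),
                    "hidden_layers": arch,
                    "val_fraction": vf,
                    "mean_accuracy": float(accs.mean()),
                    "std_accuracy": float(accs.std(ddof=1)) if k > 1 else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    best = min(
        rows,
        key=lambda r: (
            -r["mean_accuracy"],
            sum(r["hidden_layers"]),
            len(r["hidden_layers"]),
            r["val_fraction"],
        ),
    )
    return table, best


@dataclass
class Ensemble:
    """Top-N voting committee; members sorted by descending accuracy."""

    members: list[FoldResult] = field(default_factory=list)
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        accs = [m.accuracy for m in self.members]
        if any(a < b for a, b in zip(accs, accs[1:])):
            raise ValueError("members must be sorted by descending accuracy")

    @property
    def size(self) -> int:
        return len(self.members)


def select_voters(results: Sequence[FoldResult], size: int | str) -> Ensemble:
    """Pick the ``size`` most accurate networks (ties break by fold index).

    ``size`` may be ``"all"`` to keep every model. Permuting the input
    order never changes the selected set.
    """
    if size == "all":
        size = len(results)
    if not isinstance(size, int) or size < 1:
        raise ValueError(f"ensemble size must be a positive integer or 'all', got {size!r}")
    if size > len(results):
        raise ValueError(f"requested {size} voters but only {len(results)} models available")
    ranked = sorted(results, key=lambda r: (-r.accuracy, r.fold))
    return Ensemble(members=ranked[:size])


def member_outputs(ensemble: Ensemble, X: np.ndarray) -> np.ndarray:
    """(n_members, n_samples) raw outputs of every committee member."""
    X = np.atleast_2d(X)
    return np.stack([m.model.forward(X) for m in ensemble.members])


def ensemble_predict(ensemble: Ensemble, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean member output and the >0 / <=0 vote for each sample.

    A positive mean output is a positive call (the committee recognized the
    composition of a structural protein); a mean of exactly zero is a
    negative call. With all-saturated +/-1 members and an odd committee
    this reduces to majority vote.
    """
    outputs = member_outputs(ensemble, X)
    mean = outputs.mean(axis=0)
    return mean, sign_decision(mean - ensemble.decision_threshold)


def majority_predict(ensemble: Ensemble, X: np.ndarray) -> np.ndarray:
    """Strict majority vote over member sign decisions (ties -> negative)."""
    votes = sign_decision(member_outputs(ensemble, X))
    return np.where(votes.sum(axis=0) > 0, 1, -1)
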