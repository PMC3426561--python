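"""Classification metrics, ratio sweeps, and bootstrap confidence bands.

Sensitivity is the true-positive rate TP/(TP+FN) — the rate at which
structural proteins are recognized; specificity is the true-negative rate
TN/(TN+FP). Degenerate denominators yield NaN with a warning, never a
silent zero.

Confidence bands quantify the reliability of positive calls as a function
of the ensemble's mean output level: the pool of true-positive examples is
subsampled many times (a random 80% each time, without replacement), the
per-subsample accuracy at each output threshold is the fraction of the
subsample at or above the threshold, and the band is the min/max after
trimming 0.5% of subsamples from each tail — a 99%-level interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import build_dataset
from .neuralnet import TrainingConfig
from .seqfeatures import SequenceRecord
from .crossval import crossval_train, derive_seed

#: Output-threshold grid for confidence bands: 0.0 to 0.9 by 0.1.
DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(10))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(outputs: Sequence[float], labels: Sequence[int], threshold: float = 0.0) -> ConfusionCounts:
    """Tally predictions (positive iff output > threshold) against labels."""
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if outputs.shape != labels.shape:
        raise ValueError("outputs and labels must have equal length")
    if not set(np.unique(labels)) <= {1, -1}:
        raise ValueError("labels must be +1 or -1")
    predicted_pos = outputs > threshold
    actual_pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(predicted_pos & actual_pos)),
        fp=int(np.sum(predicted_pos & ~actual_pos)),
        tn=int(np.sum(~predicted_pos & ~actual_pos)),
        fn=int(np.sum(~predicted_pos & actual_pos)),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning NaN", stacklevel=3)
        return math.nan
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN); NaN when no positives were evaluated."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN/(TN+FP); NaN when no negatives were evaluated."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: ConfusionCounts) -> float:
    """Correct-classification rate (TP+TN)/total."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


# ---------------------------------------------------------------------------
# Class-ratio sweep

def ratio_sweep(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    ratios: Sequence[float] = (1, 2, 3, 4),
    include_pi_flags: Sequence[bool] = (False, True),
    hidden_layers: Sequence[int] = (5,),
    n_models: int = 10,
    val_fraction: float = 0.3,
    config: Optional[TrainingConfig] = None,
    seed: int = 0,
    **dataset_kwargs,
) -> pd.DataFrame:
    """Metrics across negatives-per-positive ratios, with and without pI.

    For each (ratio, pI flag) cell a dataset is built at that ratio and
    ``n_models`` networks are trained by ``n_models``-fold cross-validation;
    accuracy/sensitivity/specificity are computed per model on its held-out
    fold and summarized as mean +/- standard error over models.
    """
    rows = []
    for ratio in ratios:
        for include_pi in include_pi_flags:
            ds = build_dataset(
                positives,
                negatives,
                ratio=ratio,
                include_pi=include_pi,
                seed=derive_seed(seed, "dataset", ratio, include_pi),
                **dataset_kwargs,
            )
            results = crossval_train(
                ds,
                hidden_layers,
                val_fraction=val_fraction,
                k=n_models,
                config=config,
                seed=derive_seed(seed, "cv", ratio, include_pi),
            )
            per_model = {
                "accuracy": [],
                "sensitivity": [],
                "specificity": [],
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # single-class folds at high ratios
                for r in results:
                    c = confusion(r.test_outputs, r.test_labels)
                    per_model["accuracy"].append(accuracy(c))
                    per_model["sensitivity"].append(sensitivity(c))
                    per_model["specificity"].append(specificity(c))
            row = {"ratio": ratio, "include_pi": include_pi, "n_models": n_models}
            for name, vals in per_model.items():
                vals = np.asarray(vals, dtype=float)
                ok = ~np.isnan(vals)
                row[name] = float(np.mean(vals[ok])) if ok.any() else math.nan
                row[f"{name}_se"] = (
                    float(np.std(vals[ok], ddof=1) / np.sqrt(ok.sum())) if ok.sum() > 1 else math.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap confidence bands

@dataclass(frozen=True)
class ThresholdBand:
    """Trimmed min/max accuracy band for positive calls at one threshold."""

    threshold: float
    ci_low: float
    ci_high: float
    n_boot: int = 1000
    subsample_fraction: float = 0.8
    level: float = 0.99

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def bootstrap_bands(
    outputs: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_boot: int = 1000,
    fraction: float = 0.8,
    level: float = 0.99,
    seed: int = 0,
) -> list[ThresholdBand]:
    """Confidence bands of positive-prediction accuracy at output thresholds.

    The pool is the true-positive examples (labels == +1). Each of the
    ``n_boot`` subsamples draws ``fraction`` of the pool without
    replacement; its accuracy at threshold t is the fraction of drawn
    outputs >= t. The band is [min, max] after dropping
    ``(1 - level)/2 * n_boot`` subsamples at each end (5 per side at the
    defaults).
    """
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pool = outputs[labels == 1] if labels.size else outputs
    if pool.size < 5:
        raise ValueError(f"true-positive pool of {pool.size} is too small (need >= 5)")
    m = round(fraction * pool.size)
    trim = int(round(n_boot * (1.0 - level) / 2.0))
    rng = np.random.default_rng(seed)
    samples = np.stack([rng.choice(pool, size=m, replace=False) for _ in range(n_boot)])
    bands = []
    for t in thresholds:
        accs = np.sort(np.mean(samples >= t, axis=1))
        kept = accs[trim: n_boot - trim] if trim else accs
        bands.append(
            ThresholdBand(
                threshold=float(t),
                ci_low=float(kept[0]),
                ci_high=float(kept[-1]),
                n_boot=n_boot,
                subsample_fraction=fraction,
                level=level,
            )
        )
    return bands


def bands_table(bands: Sequence[ThresholdBand], seed: Optional[int] = None) -> pd.DataFrame:
    df = pd.DataFrame([vars(b) for b in bands])
    if seed is not None:
        df["seed"] = seed
    return df
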