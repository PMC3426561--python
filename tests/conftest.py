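"""Shared fixtures.

Training-heavy results (null calibration, separability, ratio-sweep trend,
ensemble comparisons, pI-feature gain) are computed once per session and
shared between the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from virionnet import make_benchmark
from virionnet.crossval import (
    crossval_train,
    ensemble_predict,
    select_voters,
    sign_decision,
)
from virionnet.evaluation import ratio_sweep
from virionnet.neuralnet import TrainingConfig
from virionnet.synthetic import make_benchmark_records


@pytest.fixture(scope="session")
def fast_config() -> TrainingConfig:
    return TrainingConfig(max_epochs=40)


@pytest.fixture(scope="session")
def null_crossval_accuracy(fast_config) -> float:
    """Mean 10-fold accuracy when the two classes are exchangeable (n=2000)."""
    ds = make_benchmark(separation=0.0, pi_shift=0.0, n_per_class=1000, seed=3)
    results = crossval_train(ds, [5], 0.2, 10, fast_config, seed=7)
    return float(np.mean([r.accuracy for r in results]))


@pytest.fixture(scope="session")
def separable_crossval_accuracy(fast_config) -> float:
    """Mean 10-fold accuracy at a composition tilt far above the noise."""
    ds = make_benchmark(separation=1.0, n_per_class=100, seed=3)
    results = crossval_train(ds, [5], 0.2, 10, fast_config, seed=7)
    return float(np.mean([r.accuracy for r in results]))


@pytest.fixture(scope="session")
def ratio_trend_table(fast_config):
    """Sensitivity/specificity across negative:positive ratios 1, 2, 4.

    Mean over two generator seeds of the per-ratio metrics from 10-model
    cross-validation at moderate class overlap.
    """
    tables = []
    for seed in (5, 6):
        pos, neg = make_benchmark_records(
            separation=0.4, n_per_class=60, n_negatives=240, seed=seed
        )
        tables.append(
            ratio_sweep(
                pos,
                neg,
                ratios=(1, 2, 4),
                include_pi_flags=(False,),
                hidden_layers=(5,),
                n_models=10,
                config=fast_config,
                seed=9 + seed,
            )
        )
    mean = tables[0][["ratio", "sensitivity", "specificity", "accuracy"]].copy()
    for col in ("sensitivity", "specificity", "accuracy"):
        mean[col] = (tables[0][col].to_numpy() + tables[1][col].to_numpy()) / 2
    return mean


@pytest.fixture(scope="session")
def ensemble_vs_single(fast_config):
    """(ensemble accuracy, best-single accuracy, min member accuracy) x 20.

    Per replicate: train 10 networks by cross-validation on one benchmark
    draw, pick the 5 most accurate, and score both the voting committee and
    its best member on an independent draw from the same generator.
    """
    rows = []
    for rep in range(20):
        train_ds = make_benchmark(separation=0.25, n_per_class=60, seed=rep * 2 + 1)
        test_ds = make_benchmark(separation=0.25, n_per_class=100, seed=1000 + rep)
        results = crossval_train(train_ds, [5], 0.2, 10, fast_config, seed=rep)
        ens = select_voters(results, 5)
        _, decision = ensemble_predict(ens, test_ds.X)
        member_accs = [
            float(np.mean(sign_decision(m.model.forward(test_ds.X)) == test_ds.y))
            for m in ens.members
        ]
        rows.append(
            {
                "ensemble": float(np.mean(decision == test_ds.y)),
                "best_single": member_accs[0],
                "min_member": min(member_accs),
            }
        )
    return rows


@pytest.fixture(scope="session")
def pi_gain_per_seed(fast_config):
    """Accuracy with vs without the pI feature on the pI-band benchmark.

    Five master seeds at 40 sequences per class: small samples are where a
    precomputed pI feature pays off most (the composition-only network must
    learn a nonlinear band in the four ionizable features from few
    examples).
    """
    pairs = []
    for seed in range(5):
        accs = {}
        for include_pi in (False, True):
            ds = make_benchmark(
                separation=0.0, pi_shift=0.5, n_per_class=40, seed=seed, include_pi=include_pi
            )
            results = crossval_train(ds, [4], 0.2, 10, fast_config, seed=seed + 100)
            accs[include_pi] = float(np.mean([r.accuracy for r in results]))
        pairs.append((accs[True], accs[False]))
    return pairs


@pytest.fixture(scope="session")
def separation_accuracies(fast_config):
    """Mean accuracy at separations 0.15/0.4/1.0, averaged over 10 seeds."""
    seps = (0.15, 0.4, 1.0)
    means = []
    for sep in seps:
        accs = []
        for seed in range(10):
            ds = make_benchmark(separation=sep, n_per_class=40, seed=50 + seed)
            results = crossval_train(ds, [5], 0.2, 5, fast_config, seed=seed)
            accs.append(np.mean([r.accuracy for r in results]))
        means.append(float(np.mean(accs)))
    return dict(zip(seps, means))
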