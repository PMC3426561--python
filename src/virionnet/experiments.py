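"""Runnable reproductions of the published training protocols.

These drive the full pipeline — featurization, class-ratio dataset
construction, cross-validated Levenberg--Marquardt training, sign-rule
accuracy — on user-supplied positive/negative protein FASTA files, at the
settings reported for the three published classifier families:

* major capsid (MCP): 1:1 ratio, one hidden layer of 40 units, 70:30
  train:validation, 10 voting networks;
* tail: as above with 10 hidden units;
* broad structural: 20x90x1, 80:20 train:validation.

The curated GenBank-derived training sets themselves are distributed as
the supplementary data of the original study and are not bundled here;
point ``pos_fasta``/``neg_fasta`` at any labeled collection to rerun the
protocol on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .curation import build_dataset
from .crossval import crossval_train, derive_seed
from .neuralnet import TrainingConfig
from .seqfeatures import SequenceRecord, clean_record, read_fasta


@dataclass(frozen=True)
class ProtocolSpec:
    """Settings of one published training protocol."""

    name: str
    hidden_layers: tuple[int, ...]
    val_fraction: float
    ratio: float = 1.0
    include_pi: bool = False
    n_models: int = 10


CAPSID_PROTOCOL = ProtocolSpec("capsid", (40,), val_fraction=0.30)
TAIL_PROTOCOL = ProtocolSpec("tail", (10,), val_fraction=0.30)
STRUCTURAL_PROTOCOL = ProtocolSpec("structural", (90,), val_fraction=0.20)

PROTOCOLS = {p.name: p for p in (CAPSID_PROTOCOL, TAIL_PROTOCOL, STRUCTURAL_PROTOCOL)}


def load_training_fastas(pos_fasta: str | Path, neg_fasta: str | Path) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Read and clean the positive/negative training FASTA files."""
    for path in (pos_fasta, neg_fasta):
        if not Path(path).exists():
            raise FileNotFoundError(
                f"training FASTA {path} not found — supply the curated positive/negative "
                f"sequence files (e.g. the study's supplementary training sets exported as FASTA)"
            )
    return (
        [clean_record(r) for r in read_fasta(pos_fasta)],
        [clean_record(r) for r in read_fasta(neg_fasta)],
    )


def run_protocol(
    protocol: ProtocolSpec,
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    master_seeds: Sequence[int] = (0, 1, 2, 3, 4),
    config: Optional[TrainingConfig] = None,
    subsample: Optional[int] = None,
) -> dict:
    """Mean held-out accuracy of the protocol over several master seeds.

    Per seed: a dataset is built at the protocol's class ratio, the
    protocol's committee of ``n_models`` networks is trained by
    ``n_models``-fold cross-validation, and accuracy is the mean
    sign-correct rate over held-out folds. ``subsample`` caps the number of
    positives (negatives scale with the ratio) for scaled-down runs.
    """
    config = config or TrainingConfig(max_epochs=100)
    per_seed = []
    for seed in master_seeds:
        pos = list(positives)
        if subsample is not None and len(pos) > subsample:
            rng = np.random.default_rng(derive_seed(seed, "subsample"))
            pos = [pos[i] for i in rng.choice(len(pos), size=subsample, replace=False)]
        ds = build_dataset(
            pos,
            negatives,
            ratio=protocol.ratio,
            include_pi=protocol.include_pi,
            seed=derive_seed(seed, "dataset", protocol.name),
            rules_name=protocol.name,
        )
        results = crossval_train(
            ds,
            protocol.hidden_layers,
            val_fraction=protocol.val_fraction,
            k=protocol.n_models,
            config=config,
            seed=derive_seed(seed, "cv", protocol.name),
        )
        per_seed.append(float(np.mean([r.accuracy for r in results])))
    return {
        "protocol": protocol.name,
        "mean_accuracy": float(np.mean(per_seed)),
        "per_seed_accuracy": per_seed,
        "n_seeds": len(per_seed),
        "n_positives_used": len(pos),
    }
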