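"""Build labeled training sets from annotated protein records.

Annotations (the free text after the FASTA id) are classified by
case-insensitive substring matching against a named keyword rule set:
uninformative qualifiers ("putative", "hypothetical protein", ...) discard a
record before any other rule fires; exclusion keywords either discard it or
route it to the negative pool (the cross-exclusion used for the capsid/tail
sets); a positive-keyword hit makes it a positive; everything else is a
negative candidate. Length filters and class-ratio construction follow.

Three rule sets ship with the package (structural, capsid, tail) as
editable YAML files; matching is plain substring on lowercased text with no
stemming, so curation is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .seqfeatures import (
    AmbiguityPolicy,
    EMBOSS_PKA,
    FeatureVector,
    PKaTable,
    SequenceRecord,
    feature_names,
    featurize_records,
)

Classification = Literal["positive", "negative", "discard"]


@dataclass(frozen=True)
class KeywordRuleSet:
    """Named keyword rules plus the minimum sequence length for one class.

    ``positive_keywords`` entries are phrases; a phrase may contain ``+`` to
    require several substrings to co-occur (e.g. ``major+capsid``).
    ``exclusion_to_negative`` selects the cross-exclusion behaviour: when
    true, excluded records become negatives instead of being discarded.
    """

    name: str
    positive_keywords: tuple[str, ...]
    exclusion_keywords: tuple[str, ...]
    uninformative_keywords: tuple[str, ...]
    min_length: int
    exclusion_to_negative: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (self.positive_keywords and self.uninformative_keywords):
            raise ValueError(f"rule set {self.name!r} has an empty keyword list")


def load_rules(name_or_path: str | Path) -> KeywordRuleSet:
    """Load a built-in rule set by name, or any rules YAML by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        ref = resources.files("virionnet").joinpath(f"data/rules/{name_or_path}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(f"no built-in rule set named {name_or_path!r}")
        raw = yaml.safe_load(ref.read_text())
    return KeywordRuleSet(
        name=raw["name"],
        positive_keywords=tuple(raw["positive_keywords"]),
        exclusion_keywords=tuple(raw.get("exclusion_keywords", ())),
        uninformative_keywords=tuple(raw["uninformative_keywords"]),
        min_length=int(raw["min_length"]),
        exclusion_to_negative=bool(raw.get("exclusion_to_negative", False)),
    )


def _phrase_matches(text: str, phrase: str) -> bool:
    return all(part in text for part in phrase.split("+"))


def classify_annotation(description: str, rules: KeywordRuleSet) -> Classification:
    """Classify an annotation string under a rule set (pure function).

    Precedence: uninformative -> discard; exclusion -> discard (or negative
    under cross-exclusion); positive keyword -> positive; otherwise the
    record is a negative candidate and ``"negative"`` is returned — it only
    enters a training set when drawn from a declared negative pool.
    """
    text = (description or "").lower()
    if any(kw in text for kw in rules.uninformative_keywords):
        return "discard"
    if any(kw in text for kw in rules.exclusion_keywords):
        return "negative" if rules.exclusion_to_negative else "discard"
    if any(_phrase_matches(text, kw) for kw in rules.positive_keywords):
        return "positive"
    return "negative"


def apply_length_filter(records: Sequence[SequenceRecord], rules: KeywordRuleSet) -> list[SequenceRecord]:
    """Keep records of at least ``rules.min_length`` residues (inclusive)."""
    return [r for r in records if len(r.residues) >= rules.min_length]


def curate(
    records: Sequence[SequenceRecord], rules: KeywordRuleSet
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split annotated records into (positives, negative candidates).

    Applies keyword classification then the rule set's length filter to
    both classes. Discarded records are dropped silently.
    """
    positives, negatives = [], []
    for rec in records:
        verdict = classify_annotation(rec.description, rules)
        if verdict == "positive":
            positives.append(rec)
        elif verdict == "negative":
            negatives.append(rec)
    return apply_length_filter(positives, rules), apply_length_filter(negatives, rules)


@dataclass
class LabeledDataset:
    """Featurized examples with +1/-1 labels and construction provenance."""

    X: np.ndarray          # (n, 20 or 21) raw features (percent scale, pI in pH units)
    y: np.ndarray          # (n,) labels in {+1, -1}
    ids: list[str]
    include_pi: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.ids):
            raise ValueError("X, y and ids must agree in length")
        if not set(np.unique(self.y)) <= {1, -1}:
            raise ValueError("labels must be +1 or -1")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in dataset")
        expected = 21 if self.include_pi else 20
        if self.X.shape[1] != expected:
            raise ValueError(f"expected {expected} features, got {self.X.shape[1]}")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            X=self.X[indices],
            y=self.y[indices],
            ids=[self.ids[i] for i in indices],
            include_pi=self.include_pi,
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=feature_names(self.include_pi))
        df.insert(0, "id", self.ids)
        df["label"] = self.y
        return df

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: Optional[dict] = None) -> "LabeledDataset":
        include_pi = "pi" in df.columns
        cols = feature_names(include_pi)
        return cls(
            X=df[cols].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            ids=[str(i) for i in df["id"]],
            include_pi=include_pi,
            provenance=provenance or {},
        )

    @classmethod
    def load_tsv(cls, path: str | Path) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"), provenance={"source": str(path)})

    @classmethod
    def from_vectors(cls, vectors: Sequence[FeatureVector], provenance: Optional[dict] = None) -> "LabeledDataset":
        if not vectors:
            raise ValueError("no feature vectors given")
        include_pi = vectors[0].pi is not None
        if any((v.pi is not None) != include_pi for v in vectors):
            raise ValueError("mixed 20- and 21-dim feature vectors")
        if any(v.label is None for v in vectors):
            raise ValueError("all vectors must be labeled")
        return cls(
            X=np.stack([v.values for v in vectors]),
            y=np.array([v.label for v in vectors]),
            ids=[v.id for v in vectors],
            include_pi=include_pi,
            provenance=provenance or {},
        )


def build_dataset(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    ratio: float = 1.0,
    include_pi: bool = False,
    seed: int = 0,
    table: PKaTable = EMBOSS_PKA,
    policy: AmbiguityPolicy = "drop-residue",
    rules_name: str = "",
) -> LabeledDataset:
    """Assemble a labeled dataset at a negatives-per-positive class ratio.

    All positives are kept; ``floor(ratio * n_pos)`` negatives are sampled
    without replacement with the given seed. The realized ratio is within
    one count of the request. Raises when the negative pool is short or an
    id would appear twice.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not positives:
        raise ValueError("no positive examples")
    n_neg = math.floor(ratio * len(positives))
    if n_neg > len(negatives):
        raise ValueError(
            f"need {n_neg} negatives for ratio {ratio} with {len(positives)} positives, "
            f"have {len(negatives)} (short by {n_neg - len(negatives)})"
        )
    rng = np.random.default_rng(seed)
    chosen = [negatives[i] for i in rng.choice(len(negatives), size=n_neg, replace=False)]
    pos_ids = {r.id for r in positives}
    if len(pos_ids) != len(positives) or pos_ids & {r.id for r in chosen}:
        raise ValueError("duplicate ids across or within classes")
    vectors = featurize_records(positives, include_pi, table, policy, label=1)
    vectors += featurize_records(chosen, include_pi, table, policy, label=-1)
    return LabeledDataset.from_vectors(
        vectors,
        provenance={
            "rules": rules_name,
            "ratio": ratio,
            "seed": seed,
            "n_positive": len(positives),
            "n_negative": n_neg,
            "include_pi": include_pi,
            "pka_table": table.name if include_pi else None,
        },
    )
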