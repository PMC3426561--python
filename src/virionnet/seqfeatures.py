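"""Protein sequence records and the numeric features the networks consume.

A protein is represented to the classifier by its amino-acid percent
composition (20 values summing to 100, one per standard residue in
alphabetical one-letter order) and, optionally, its isoelectric point (pI).
The pI is the pH at which the modeled net charge of the protein is zero
under Henderson--Hasselbalch ionization of the titratable side chains
(D, E, C, Y, H, K, R) and the two termini; it is found by bisection, since
net charge is strictly decreasing in pH.

Composition features are order-insensitive by construction, which is the
point: structural proteins of phages share almost no detectable sequence
similarity, so the classifier works from residue usage alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue ordering used for every 20-dim composition vector,
#: fixed project-wide: alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Codes that are legal in input files but not part of the 20-letter alphabet.
AMBIGUOUS_CODES = frozenset("BJZXUO")

AmbiguityPolicy = Literal["drop-residue", "reject"]


class SequenceError(ValueError):
    """Raised for malformed or empty sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its identifier and free-text annotation."""

    id: str
    description: str = ""
    residues: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence record requires a non-empty id")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PKaTable:
    """Named pKa set for the titratable groups used in net-charge/pI estimates.

    ``side`` holds side-chain pKa values for D, E, C, Y (acidic) and
    H, K, R (basic); ``nterm``/``cterm`` are the terminal amine/carboxyl
    pKa values. All entries are pH units in (0, 14). Tables are named so a
    pI value can always be traced to the constants that produced it.
    """

    name: str
    nterm: float
    cterm: float
    side: dict = field(default_factory=dict)

    ACIDIC = ("D", "E", "C", "Y")
    BASIC = ("K", "R", "H")

    def __post_init__(self) -> None:
        values = [self.nterm, self.cterm, *self.side.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError(f"pKa table {self.name!r} has values outside (0, 14)")
        missing = set(self.ACIDIC + self.BASIC) - set(self.side)
        if missing:
            raise ValueError(f"pKa table {self.name!r} missing side chains: {sorted(missing)}")


#: Default table: the EMBOSS constants used by the BioPerl pI calculator.
EMBOSS_PKA = PKaTable(
    name="emboss",
    nterm=8.6,
    cterm=3.6,
    side={"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1},
)

#: Bjellqvist-style alternative (single generic terminal pKa values).
BJELLQVIST_PKA = PKaTable(
    name="bjellqvist",
    nterm=7.5,
    cterm=3.55,
    side={"C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0},
)

PKA_TABLES = {t.name: t for t in (EMBOSS_PKA, BJELLQVIST_PKA)}


@dataclass(frozen=True)
class FeatureVector:
    """Numeric encoding of one protein: composition (+ optional pI, label)."""

    composition: np.ndarray  # 20 percentages, canonical order, sum 100
    pi: Optional[float] = None
    label: Optional[int] = None
    id: str = ""

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        object.__setattr__(self, "composition", comp)
        if comp.shape != (20,):
            raise ValueError(f"composition must have 20 entries, got {comp.shape}")
        if np.any(comp < 0) or abs(comp.sum() - 100.0) > 1e-9:
            raise ValueError("composition must be non-negative and sum to 100")
        if self.pi is not None and not (0.0 <= self.pi <= 14.0):
            raise ValueError(f"pI {self.pi} outside [0, 14]")
        if self.label is not None and self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")

    @property
    def values(self) -> np.ndarray:
        """20- or 21-dim network input (pI appended when present)."""
        if self.pi is None:
            return self.composition
        return np.append(self.composition, self.pi)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    The header line is split into the id (first whitespace token) and the
    description (remainder). Residues are uppercased but not cleaned; run
    :func:`clean_sequence` before computing features.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(i for i, line in enumerate(text.splitlines(), 1) if line.strip())
        raise SequenceError(f"{path}: not FASTA — sequence data before any '>' header at line {first_bad}")
    records = [
        SequenceRecord(
            id=rec.id,
            description=rec.description[len(rec.id):].strip(),
            residues=str(rec.seq).upper(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-line FASTA (inverse of :func:`read_fasta`)."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Cleaning and composition

def clean_sequence(residues: str, policy: AmbiguityPolicy = "drop-residue") -> str:
    """Normalize a raw residue string to the 20-letter alphabet.

    Stop characters (``*``), gaps and whitespace are always removed.
    Ambiguous or non-standard codes are removed under ``"drop-residue"``
    (the default) or raise under ``"reject"``.
    """
    if not residues:
        raise SequenceError("empty sequence")
    if policy not in ("drop-residue", "reject"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    kept = []
    for pos, ch in enumerate(residues.upper(), start=1):
        if ch in _AA_INDEX:
            kept.append(ch)
            continue
        if ch in "*-." or ch.isspace():
            continue
        if policy == "reject":
            raise SequenceError(f"non-standard residue {ch!r} at position {pos}")
        # drop-residue: ambiguous (B, J, Z, X, U, O) and any other junk removed
    cleaned = "".join(kept)
    if not cleaned:
        raise SequenceError("sequence empty after cleaning")
    return cleaned


def clean_record(record: SequenceRecord, policy: AmbiguityPolicy = "drop-residue") -> SequenceRecord:
    return replace(record, residues=clean_sequence(record.residues, policy))


def aa_composition(residues: str) -> np.ndarray:
    """Percent composition of the 20 standard amino acids (canonical order).

    Returns 100 * count(a) / len for each residue a; entries sum to 100.
    The input must already be cleaned to the 20-letter alphabet.
    """
    if not residues:
        raise SequenceError("cannot compute composition of an empty sequence")
    counts = np.zeros(20)
    for ch in residues:
        try:
            counts[_AA_INDEX[ch]] += 1
        except KeyError:
            raise SequenceError(f"non-standard residue {ch!r}; clean the sequence first") from None
    return counts * (100.0 / len(residues))


# ---------------------------------------------------------------------------
# Net charge and isoelectric point

def _group_counts(residues: str, table: PKaTable) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(count, pKa) pairs for basic and acidic groups, termini included."""
    basic = [(float(residues.count(aa)), table.side[aa]) for aa in PKaTable.BASIC]
    basic.append((1.0, table.nterm))
    acidic = [(float(residues.count(aa)), table.side[aa]) for aa in PKaTable.ACIDIC]
    acidic.append((1.0, table.cterm))
    return basic, acidic


def net_charge(residues: str, ph: float, table: PKaTable = EMBOSS_PKA) -> float:
    """Henderson--Hasselbalch net charge of a cleaned sequence at a given pH.

    charge = sum over basic groups g of n_g / (1 + 10^(pH - pKa_g))
           - sum over acidic groups g of n_g / (1 + 10^(pKa_g - pH))

    Basic groups are K, R, H side chains and the N-terminus; acidic groups
    are D, E, C, Y side chains and the C-terminus. Strictly decreasing in pH.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    basic, acidic = _group_counts(residues, table)
    charge = sum(n / (1.0 + 10.0 ** (ph - pka)) for n, pka in basic)
    charge -= sum(n / (1.0 + 10.0 ** (pka - ph)) for n, pka in acidic)
    return charge


def isoelectric_point(residues: str, table: PKaTable = EMBOSS_PKA, tol: float = 1e-3) -> float:
    """pH at which :func:`net_charge` is zero, by bisection on [0, 14].

    The charge is strictly monotone decreasing in pH and is positive at
    pH 0 (protonated N-terminus) and negative at pH 14 (deprotonated
    C-terminus), so the root exists and is unique. Deterministic for a
    fixed table; the result is within ``tol`` of the true root.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid, table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Featurization

def featurize(
    record: SequenceRecord,
    include_pi: bool = False,
    table: PKaTable = EMBOSS_PKA,
    policy: AmbiguityPolicy = "drop-residue",
    label: Optional[int] = None,
) -> FeatureVector:
    """Convert one record into a 20- or 21-dim network input."""
    cleaned = clean_sequence(record.residues, policy)
    comp = aa_composition(cleaned)
    pi = isoelectric_point(cleaned, table) if include_pi else None
    return FeatureVector(composition=comp, pi=pi, label=label, id=record.id)


def featurize_records(
    records: Sequence[SequenceRecord],
    include_pi: bool = False,
    table: PKaTable = EMBOSS_PKA,
    policy: AmbiguityPolicy = "drop-residue",
    label: Optional[int] = None,
) -> list[FeatureVector]:
    """Order-preserving batch :func:`featurize`."""
    return [featurize(r, include_pi, table, policy, label) for r in records]


def feature_names(include_pi: bool) -> list[str]:
    names = list(AMINO_ACIDS)
    if include_pi:
        names.append("pi")
    return names


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Long-format table: id, 20 composition columns, pi/label when present."""
    rows = []
    for v in vectors:
        row = {"id": v.id, **{aa: v.composition[i] for i, aa in enumerate(AMINO_ACIDS)}}
        if v.pi is not None:
            row["pi"] = v.pi
        if v.label is not None:
            row["label"] = v.label
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_tsv(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    feature_table(vectors).to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path, sep="\t")
    vectors = []
    for _, row in df.iterrows():
        vectors.append(
            FeatureVector(
                composition=row[list(AMINO_ACIDS)].to_numpy(dtype=float),
                pi=float(row["pi"]) if "pi" in df.columns and pd.notna(row.get("pi")) else None,
                label=int(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else None,
                id=str(row["id"]),
            )
        )
    return vectors


# ---------------------------------------------------------------------------
# Redundancy removal

def _make_aligner() -> PairwiseAligner:
    # Global alignment scoring: match 1, mismatch 0, tiny linear gap penalty
    # so that the optimal alignment maximizes matches while staying compact.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.01
    aligner.extend_gap_score = -0.01
    return aligner


def pairwise_identity(a: str, b: str, aligner: Optional[PairwiseAligner] = None) -> float:
    """Global identity = matches / alignment columns under simple scoring."""
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def dedup_90(records: Sequence[SequenceRecord], threshold: float = 0.9) -> list[SequenceRecord]:
    """Greedy centroid clustering at >= ``threshold`` global identity.

    Records are visited longest-first (ties keep input order). A record
    joins the first existing cluster whose representative it matches at or
    above the identity threshold; otherwise it founds a new cluster. The
    representatives (cluster founders) are returned in founding order, so
    the result is deterministic for a given input. Idempotent: running the
    output through again returns it unchanged.
    """
    aligner = _make_aligner()
    ordered = sorted(enumerate(records), key=lambda ir: (-len(ir[1].residues), ir[0]))
    representatives: list[SequenceRecord] = []
    for _, rec in ordered:
        if not any(
            pairwise_identity(rec.residues, rep.residues, aligner) >= threshold
            for rep in representatives
        ):
            representatives.append(rec)
    return representatives
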