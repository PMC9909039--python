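"""Peptide records, FASTA I/O and stratified dataset splitting.

Peptides are short sequences over the 20 standard amino acids. The positive
class (label 1) is "bitter", the negative class (label 0) "non-bitter",
following the usual convention in taste-peptide benchmarks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "STANDARD_RESIDUES",
    "Peptide",
    "LabeledDataset",
    "SequenceValidationError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
    "stratified_split",
]

#: The 20 standard one-letter amino acid codes, alphabetical.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_SET = frozenset(STANDARD_RESIDUES)


class SequenceValidationError(ValueError):
    """A peptide sequence violates the 20-letter alphabet or length rules."""


class FastaParseError(ValueError):
    """A FASTA file could not be parsed."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with identifier and optional label.

    Parameters
    ----------
    id : str
        Record identifier, unique within a dataset.
    sequence : str
        Uppercase sequence over the 20 standard one-letter codes; length
        must be at least 2 (dipeptide descriptors and lag-1 correlation
        factors need two residues).
    label : int or None
        1 = bitter (positive), 0 = non-bitter (negative), None = unlabeled.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise SequenceValidationError(
                f"peptide {self.id!r}: length {len(seq)} < 2"
            )
        bad = set(seq) - _RESIDUE_SET
        if bad:
            raise SequenceValidationError(
                f"peptide {self.id!r}: non-standard residue(s) "
                f"{sorted(bad)} (allowed: {STANDARD_RESIDUES})"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"peptide {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of peptides with unique ids.

    For labeled operations (splitting, training) every member must carry a
    binary label; unlabeled collections are allowed for prediction-time use.
    """

    peptides: list[Peptide] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide ids: {dupes}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def labels(self) -> np.ndarray:
        """Label vector; raises if any peptide is unlabeled."""
        if any(p.label is None for p in self.peptides):
            missing = [p.id for p in self.peptides if p.label is None][:5]
            raise ValueError(f"unlabeled peptides present, e.g. {missing}")
        return np.array([p.label for p in self.peptides], dtype=int)

    def class_counts(self) -> dict[int, int]:
        y = self.labels
        return {1: int((y == 1).sum()), 0: int((y == 0).sum())}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.peptides[i] for i in indices])

    def with_labels(self, labels: Mapping[str, int]) -> "LabeledDataset":
        missing = [p.id for p in self.peptides if p.id not in labels]
        if missing:
            raise ValueError(f"no label for ids: {missing[:5]}")
        return LabeledDataset(
            [replace(p, label=int(labels[p.id])) for p in self.peptides]
        )


def read_fasta(
    path: str | Path,
    label: int | None = None,
    labels: Mapping[str, int] | None = None,
    drop_invalid: bool = False,
) -> LabeledDataset:
    """Read a peptide FASTA file into a :class:`LabeledDataset`.

    Parameters
    ----------
    path : path
        Multi-record FASTA; wrapped or unwrapped lines accepted.
    label : int, optional
        Label assigned to every record (two-FASTA convention: one file of
        positives, one of negatives).
    labels : mapping id -> {0,1}, optional
        Per-record labels, e.g. from :func:`read_label_table`. Mutually
        exclusive with ``label``.
    drop_invalid : bool
        If True, silently drop records failing validation instead of
        raising. Off by default: a non-standard residue is an error.
    """
    if label is not None and labels is not None:
        raise ValueError("pass either 'label' or 'labels', not both")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[Peptide] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio.SeqIO raises ValueError subclasses
        raise FastaParseError(f"{path}: {exc}") from exc
    # SeqIO silently ignores leading junk; treat non-empty non-FASTA as error
    if not records:
        text = path.read_text().strip()
        if text and not text.startswith(">"):
            raise FastaParseError(f"{path}: not a FASTA file (no '>' records)")
    for rec in records:
        rec_label = label if labels is None else labels.get(rec.id)
        if labels is not None and rec_label is None:
            raise ValueError(f"{path}: no label for record {rec.id!r}")
        try:
            peptides.append(Peptide(rec.id, str(rec.seq), rec_label))
        except SequenceValidationError:
            if not drop_invalid:
                raise
    return LabeledDataset(peptides)


def write_fasta(dataset: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for p in dataset:
            fh.write(f">{p.id}\n{p.sequence}\n")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a TSV of ``id<TAB>label`` rows (header optional) into a dict."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "id" and row[1] == "label":
                continue
            ident, lab = row[0], row[1]
            if lab not in ("0", "1"):
                raise ValueError(f"label for {ident!r} must be 0 or 1, got {lab!r}")
            out[ident] = int(lab)
    return out


def write_label_table(dataset: Iterable[Peptide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for p in dataset:
            fh.write(f"{p.id}\t{p.label}\n")


def stratified_split(
    data: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a labeled dataset into train/independent partitions per class.

    Within each class the members are shuffled with a seeded generator and
    the first ``round(train_fraction * class_size)`` go to the training
    partition, so e.g. 320 + 320 peptides at 0.8 yield 256 + 256 train and
    64 + 64 held out. Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = data.labels
    counts = data.class_counts()
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(f"each class needs >= 2 members, got {counts}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        n_train = round(train_fraction * len(idx))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    # keep original dataset order within each partition
    return data.subset(sorted(train_idx)), data.subset(sorted(test_idx))
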