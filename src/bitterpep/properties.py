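"""Physicochemical scales and residue distance matrices.

Houses the per-residue property scales (hydrophobicity, hydrophilicity,
side-chain mass) and the pairwise distance matrices consumed by the
pseudo-amino-acid, sequence-order-coupling and quasi-sequence-order
descriptors, together with their standard-normal normalization.

Shipped tables (``bitterpep/data/*.tsv``, residue rows alphabetical
A,C,D,...,Y):

- ``hydrophobicity.tsv``, ``hydrophilicity.tsv``, ``side_chain_mass.tsv`` —
  the canonical type-1 PseAAC scales (Eisenberg-consensus hydrophobicity,
  Hopp–Woods hydrophilicity, side-chain masses).
- ``grantham.tsv`` — the Grantham (1974) chemical distance matrix, unscaled.
- ``schneider_wrede_synthetic.tsv`` — a constructed stand-in for the
  Schneider–Wrede physicochemical distance matrix: the max-normalized
  Euclidean distance between residues in the space of the three normalized
  scales above. Synthetic: it preserves the structure of a physicochemical
  distance (symmetric, zero diagonal, values in [0, 1]) but is not the
  published table; supply your own TSV via :func:`load_distance_matrix` to
  use a different matrix.

All scale normalization follows the standard-normal convention: subtract
the 20-residue mean and divide by the root mean squared deviation (the
population standard deviation over the 20 residues).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .peptides import STANDARD_RESIDUES

__all__ = [
    "ResidueScale",
    "DistanceMatrix",
    "CODON_COUNTS",
    "TOTAL_CODONS",
    "load_scale",
    "load_distance_matrix",
    "normalize_scale",
    "default_scales",
    "default_distance_matrices",
    "correlation_theta",
    "hydro_correlations",
]

#: Sense-codon multiplicities of the standard genetic code (61 total; the
#: three stop codons are excluded).
CODON_COUNTS: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}
TOTAL_CODONS = 61
assert sum(CODON_COUNTS.values()) == TOTAL_CODONS


@dataclass(frozen=True)
class ResidueScale:
    """A per-residue property scale over the 20 standard residues."""

    name: str
    values: tuple[float, ...]  # ordered as STANDARD_RESIDUES
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"scale {self.name!r} needs 20 values")

    def __getitem__(self, residue: str) -> float:
        return self.values[STANDARD_RESIDUES.index(residue)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STANDARD_RESIDUES, self.values))


@dataclass(frozen=True)
class DistanceMatrix:
    """A 20x20 nonnegative residue distance matrix with zero diagonal."""

    name: str
    values: np.ndarray  # (20, 20), indexed by STANDARD_RESIDUES position

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError(f"matrix {self.name!r} must be 20x20")
        if (v < 0).any():
            raise ValueError(f"matrix {self.name!r} has negative entries")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError(f"matrix {self.name!r} diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = STANDARD_RESIDUES.index(pair[0])
        j = STANDARD_RESIDUES.index(pair[1])
        return float(self.values[i, j])


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bitterpep").joinpath("data", name)))


def load_scale(source: str | Path, name: str | None = None) -> ResidueScale:
    """Load a raw scale from a two-column TSV (residue, value).

    ``source`` may be a shipped table name (``hydrophobicity``,
    ``hydrophilicity``, ``side_chain_mass``) or a path to a user TSV.
    """
    path = Path(source)
    if not path.exists():
        path = _data_path(f"{source}.tsv")
    vals: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0] in ("residue", "#"):
                continue
            vals[row[0]] = float(row[1])
    missing = set(STANDARD_RESIDUES) - set(vals)
    if missing:
        raise ValueError(f"{path}: missing residues {sorted(missing)}")
    return ResidueScale(
        name or path.stem, tuple(vals[r] for r in STANDARD_RESIDUES)
    )


def load_distance_matrix(source: str | Path, name: str | None = None) -> DistanceMatrix:
    """Load a 20x20 distance matrix from TSV with residue header row/column."""
    path = Path(source)
    if not path.exists():
        path = _data_path(f"{source}.tsv")
    with open(path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r]
    header = rows[0][1:]
    if sorted(header) != sorted(STANDARD_RESIDUES):
        raise ValueError(f"{path}: header must list the 20 standard residues")
    mat = np.zeros((20, 20))
    for row in rows[1:]:
        i = STANDARD_RESIDUES.index(row[0])
        for col, val in zip(header, row[1:]):
            mat[i, STANDARD_RESIDUES.index(col)] = float(val)
    return DistanceMatrix(name or path.stem, mat)


def normalize_scale(raw: ResidueScale) -> ResidueScale:
    """Standard-normal normalization of a residue scale.

    Subtracts the mean over the 20 residues and divides by the root mean
    squared deviation, so the result has mean 0 and unit RMS deviation.
    Idempotent; invariant under positive affine transforms of the input.
    """
    v = raw.as_array()
    centered = v - v.mean()
    denom = np.sqrt((centered**2).mean())
    if denom == 0.0:
        raise ValueError(f"scale {raw.name!r} is constant: zero denominator")
    return ResidueScale(raw.name, tuple(centered / denom), normalized=True)


_DEFAULT_SCALE_NAMES = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


def default_scales(normalized: bool = True) -> tuple[ResidueScale, ...]:
    """The three shipped scales (H1, H2, M), normalized by default."""
    scales = tuple(load_scale(n) for n in _DEFAULT_SCALE_NAMES)
    if normalized:
        scales = tuple(normalize_scale(s) for s in scales)
    return scales


def default_distance_matrices() -> tuple[DistanceMatrix, DistanceMatrix]:
    """Shipped matrices in fixed order: Schneider–Wrede-style first, Grantham second."""
    return (
        load_distance_matrix("schneider_wrede_synthetic", name="SchneiderWrede"),
        load_distance_matrix("grantham", name="Grantham"),
    )


def correlation_theta(
    r_i: str, r_j: str, scales: tuple[ResidueScale, ...] | None = None
) -> float:
    """Three-property residue correlation: mean squared difference of the
    normalized hydrophobicity, hydrophilicity and side-chain mass.

    Symmetric in its arguments, nonnegative, and zero iff the residues have
    identical property values (in particular on the diagonal).
    """
    scales = scales or default_scales()
    return float(
        np.mean([(s[r_i] - s[r_j]) ** 2 for s in scales])
    )


def hydro_correlations(
    r_i: str, r_j: str, scales: tuple[ResidueScale, ...] | None = None
) -> tuple[float, float]:
    """Amphiphilic correlation pair: products H1(i)H1(j) and H2(i)H2(j) of the
    normalized hydrophobicity and hydrophilicity values."""
    scales = scales or default_scales()
    h1, h2 = scales[0], scales[1]
    return (h1[r_i] * h1[r_j], h2[r_i] * h2[r_j])
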