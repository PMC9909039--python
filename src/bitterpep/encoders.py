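"""The ten peptide descriptor families.

Each encoder is a pure function from a peptide sequence to a named,
ordered numeric feature vector:

========== ===== ==============================================================
Encoder    Dim   Description
========== ===== ==============================================================
AAC        20    amino acid composition (residue frequencies)
TPAAC      20+λ  type-1 pseudo-amino-acid composition: AAC plus λ
                 sequence-order correlation factors built from the three
                 normalized physicochemical scales
APAAC      20+2λ amphiphilic PseAAC: AAC plus hydrophobicity/hydrophilicity
                 product correlation factors, interleaved by lag
ASDC       400   adaptive skip dipeptide composition: ordered residue pairs
                 at every gap up to N−1, normalized by the pair total
DPC        400   adjacent dipeptide composition
DDE        400   dipeptide deviation from expected mean, standardized against
                 the codon-usage expectation (61 sense codons)
GAAC       5     grouped AAC over five physicochemical residue groups
GDPC       25    grouped dipeptide composition
SOCNumber  2·g   sequence-order-coupling numbers: lag-d sums of squared
                 residue distances, per distance matrix (g = nlag)
QSOrder    2·(20+g) quasi-sequence-order: residue frequencies plus coupling
                 numbers sharing one denominator, per distance matrix
========== ===== ==============================================================

Default parameters are λ = 1 and nlag = 1 (the largest values valid for
dipeptides, and the ones that give the dimensions above, 1,337 in total),
with weights ω = 0.05 (TPAAC), w = 0.5 (APAAC) and w = 0.1 (QSOrder).

Component order is fixed and documented so feature matrices are
column-stable: residues alphabetical by one-letter code, dipeptides
row-major (first residue in the outer loop), groups g1..g5, distance-matrix
blocks Schneider–Wrede-style first then Grantham.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .peptides import STANDARD_RESIDUES, Peptide
from .properties import (
    CODON_COUNTS,
    TOTAL_CODONS,
    DistanceMatrix,
    ResidueScale,
    default_distance_matrices,
    default_scales,
)

__all__ = [
    "ENCODER_ORDER",
    "RESIDUE_GROUPS",
    "EncoderConfig",
    "FeatureVector",
    "EncodingLengthError",
    "PeptideEncoder",
    "encode_aac",
    "encode_tpaac",
    "encode_apaac",
    "encode_asdc",
    "encode_dpc",
    "encode_dde",
    "encode_gaac",
    "encode_gdpc",
    "encode_socnumber",
    "encode_qsorder",
    "encode_all",
]

#: Fixed application/concatenation order of the ten encoders.
ENCODER_ORDER = (
    "AAC", "TPAAC", "APAAC", "ASDC", "DPC", "DDE",
    "GAAC", "GDPC", "SOCNumber", "QSOrder",
)

#: Five physicochemical residue groups: aliphatic, aromatic, positively
#: charged, negatively charged, uncharged polar/small.
RESIDUE_GROUPS: dict[str, str] = {
    "g1": "GAVLMI",
    "g2": "FYW",
    "g3": "KRH",
    "g4": "DE",
    "g5": "STCPNQ",
}

_GROUP_NAMES = tuple(RESIDUE_GROUPS)
_GROUP_OF = np.empty(20, dtype=int)
for _g, (_name, _members) in enumerate(RESIDUE_GROUPS.items()):
    for _r in _members:
        _GROUP_OF[STANDARD_RESIDUES.index(_r)] = _g

_DIPEPTIDES = tuple(a + b for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES)
_GROUP_PAIRS = tuple(f"{a}.{b}" for a in _GROUP_NAMES for b in _GROUP_NAMES)
_CODONS = np.array([CODON_COUNTS[r] for r in STANDARD_RESIDUES], dtype=float)


class EncodingLengthError(ValueError):
    """Peptide too short for the requested lag parameter."""


@dataclass(frozen=True)
class FeatureVector:
    """A named, ordered numeric descriptor vector for one peptide."""

    encoder: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(self.names) != v.size:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        if not np.isfinite(v).all():
            raise ValueError(f"{self.encoder}: non-finite component")
        object.__setattr__(self, "values", v)

    @property
    def qualified_names(self) -> tuple[str, ...]:
        return tuple(f"{self.encoder}.{n}" for n in self.names)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable encoder parameters.

    lambda_ and nlag must stay below the length of every peptide encoded
    (checked at encode time); all weights must be positive.
    """

    lambda_: int = 1
    omega_tpaac: float = 0.05
    w_apaac: float = 0.5
    w_qsorder: float = 0.1
    nlag: int = 1
    scales: tuple[ResidueScale, ...] | None = None
    matrices: tuple[DistanceMatrix, ...] | None = None

    def __post_init__(self) -> None:
        if self.lambda_ < 1 or self.nlag < 1:
            raise ValueError("lambda_ and nlag must be positive integers")
        if min(self.omega_tpaac, self.w_apaac, self.w_qsorder) <= 0:
            raise ValueError("weights must be > 0")


class _Tables:
    """Pre-tabulated lookups shared by all encoders for one config."""

    def __init__(self, cfg: EncoderConfig):
        scales = cfg.scales or _default_scales_cached()
        if len(scales) < 2:
            raise ValueError("need at least two scales (hydrophobicity first)")
        # Theta(i, j): mean squared property difference over however many
        # scales are configured (three classic ones by default)
        props = np.stack([s.as_array() for s in scales])
        self.theta = ((props[:, :, None] - props[:, None, :]) ** 2).mean(axis=0)
        h1, h2 = scales[0].as_array(), scales[1].as_array()
        self.h1_prod = np.outer(h1, h1)
        self.h2_prod = np.outer(h2, h2)
        mats = cfg.matrices or _default_matrices_cached()
        self.matrix_names = tuple(m_.name for m_ in mats)
        self.dist_sq = tuple(m_.values**2 for m_ in mats)


@lru_cache(maxsize=1)
def _default_scales_cached() -> tuple[ResidueScale, ...]:
    return default_scales()


@lru_cache(maxsize=1)
def _default_matrices_cached() -> tuple[DistanceMatrix, ...]:
    return default_distance_matrices()


_TABLE_CACHE: dict[EncoderConfig, _Tables] = {}


def _tables(cfg: EncoderConfig) -> _Tables:
    if cfg.scales is not None or cfg.matrices is not None:
        return _Tables(cfg)  # custom tables: not hashable, skip the cache
    tab = _TABLE_CACHE.get(cfg)
    if tab is None:
        if len(_TABLE_CACHE) > 32:
            _TABLE_CACHE.clear()
        tab = _TABLE_CACHE[cfg] = _Tables(cfg)
    return tab


_RESIDUE_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


def _indices(p: Peptide | str) -> np.ndarray:
    # validation (alphabet, length >= 2) happens in the Peptide constructor
    seq = p.sequence if isinstance(p, Peptide) else Peptide("_", str(p)).sequence
    return np.array([_RESIDUE_INDEX[c] for c in seq], dtype=int)


def _check_lag(idx: np.ndarray, lag: int, what: str) -> None:
    if len(idx) <= lag:
        raise EncodingLengthError(
            f"peptide length {len(idx)} must exceed {what}={lag}"
        )


def _counts(idx: np.ndarray) -> np.ndarray:
    return np.bincount(idx, minlength=20).astype(float)


# ---------------------------------------------------------------------------
# the ten encoders


def encode_aac(p: Peptide | str) -> FeatureVector:
    """Amino acid composition: frequency of each of the 20 residues."""
    idx = _indices(p)
    return FeatureVector("AAC", tuple(STANDARD_RESIDUES), _counts(idx) / len(idx))


def _theta_factors(idx: np.ndarray, lam: int, theta: np.ndarray) -> np.ndarray:
    n = len(idx)
    return np.array(
        [theta[idx[:-d], idx[d:]].sum() / (n - d) for d in range(1, lam + 1)]
    )


def encode_tpaac(p: Peptide | str, cfg: EncoderConfig = EncoderConfig()) -> FeatureVector:
    """Type-1 pseudo-amino-acid composition (20 + λ components).

    The first 20 components are residue frequencies and the last λ are
    weighted sequence-order correlation factors θ_d (means of the
    three-property correlation over residue pairs at lag d); all share the
    denominator 1 + ω Σθ, so the vector sums to 1.
    """
    idx = _indices(p)
    _check_lag(idx, cfg.lambda_, "lambda")
    tab = _tables(cfg)
    theta = _theta_factors(idx, cfg.lambda_, tab.theta)
    freqs = _counts(idx) / len(idx)
    denom = freqs.sum() + cfg.omega_tpaac * theta.sum()
    values = np.concatenate([freqs, cfg.omega_tpaac * theta]) / denom
    names = tuple(STANDARD_RESIDUES) + tuple(
        f"lambda{d}" for d in range(1, cfg.lambda_ + 1)
    )
    return FeatureVector("TPAAC", names, values)


def encode_apaac(p: Peptide | str, cfg: EncoderConfig = EncoderConfig()) -> FeatureVector:
    """Amphiphilic PseAAC (20 + 2λ components).

    Correlation factors τ are lag-d means of pairwise products of the
    normalized hydrophobicity (odd positions) and hydrophilicity (even
    positions) values, interleaved as (hydrophobicity lag 1, hydrophilicity
    lag 1, hydrophobicity lag 2, ...).
    """
    idx = _indices(p)
    _check_lag(idx, cfg.lambda_, "lambda")
    tab = _tables(cfg)
    n = len(idx)
    taus = []
    for d in range(1, cfg.lambda_ + 1):
        taus.append(tab.h1_prod[idx[:-d], idx[d:]].sum() / (n - d))
        taus.append(tab.h2_prod[idx[:-d], idx[d:]].sum() / (n - d))
    taus = np.array(taus)
    freqs = _counts(idx) / n
    denom = freqs.sum() + cfg.w_apaac * taus.sum()
    values = np.concatenate([freqs, cfg.w_apaac * taus]) / denom
    names = tuple(STANDARD_RESIDUES) + tuple(
        f"{prop}.lag{d}"
        for d in range(1, cfg.lambda_ + 1)
        for prop in ("hydrophobicity", "hydrophilicity")
    )
    return FeatureVector("APAAC", names, values)


def encode_asdc(p: Peptide | str) -> FeatureVector:
    """Adaptive skip dipeptide composition (400 components).

    Counts every ordered residue pair (i, j) with i < j — adjacent and
    intervening alike — and divides by the total pair count N(N−1)/2.
    """
    idx = _indices(p)
    n = len(idx)
    counts = np.zeros((20, 20))
    for g in range(1, n):
        np.add.at(counts, (idx[:-g], idx[g:]), 1.0)
    return FeatureVector(
        "ASDC", _DIPEPTIDES, counts.ravel() / (n * (n - 1) / 2)
    )


def _dipeptide_counts(idx: np.ndarray) -> np.ndarray:
    counts = np.zeros((20, 20))
    np.add.at(counts, (idx[:-1], idx[1:]), 1.0)
    return counts


def encode_dpc(p: Peptide | str) -> FeatureVector:
    """Adjacent dipeptide composition: N_rs / (N − 1) over 400 ordered pairs."""
    idx = _indices(p)
    return FeatureVector(
        "DPC", _DIPEPTIDES, _dipeptide_counts(idx).ravel() / (len(idx) - 1)
    )


def encode_dde(p: Peptide | str) -> FeatureVector:
    """Dipeptide deviation from expected mean (400 components).

    Standardizes the observed dipeptide composition D_c against its
    codon-usage expectation: T_m(r,s) = (C_r/61)(C_s/61), variance
    T_v = T_m(1−T_m)/(N−1), giving DDE = (D_c − T_m)/√T_v.
    """
    idx = _indices(p)
    n = len(idx)
    dc = _dipeptide_counts(idx) / (n - 1)
    frac = _CODONS / TOTAL_CODONS
    tm = np.outer(frac, frac)
    tv = tm * (1.0 - tm) / (n - 1)
    return FeatureVector("DDE", _DIPEPTIDES, ((dc - tm) / np.sqrt(tv)).ravel())


def encode_gaac(p: Peptide | str) -> FeatureVector:
    """Grouped amino acid composition over the five residue groups."""
    idx = _indices(p)
    counts = np.bincount(_GROUP_OF[idx], minlength=5).astype(float)
    return FeatureVector("GAAC", _GROUP_NAMES, counts / len(idx))


def encode_gdpc(p: Peptide | str) -> FeatureVector:
    """Grouped dipeptide composition (25 components) over adjacent pairs."""
    idx = _GROUP_OF[_indices(p)]
    counts = np.zeros((5, 5))
    np.add.at(counts, (idx[:-1], idx[1:]), 1.0)
    return FeatureVector("GDPC", _GROUP_PAIRS, counts.ravel() / (len(idx) - 1))


def _coupling_numbers(idx: np.ndarray, nlag: int, dist_sq: np.ndarray) -> np.ndarray:
    return np.array(
        [dist_sq[idx[:-d], idx[d:]].sum() for d in range(1, nlag + 1)]
    )


def encode_socnumber(p: Peptide | str, cfg: EncoderConfig = EncoderConfig()) -> FeatureVector:
    """Sequence-order-coupling numbers (2·nlag components).

    τ_d = Σ_i d(r_i, r_{i+d})² for d = 1..nlag, computed for each of the two
    distance matrices; components ordered matrix-major.
    """
    idx = _indices(p)
    _check_lag(idx, cfg.nlag, "nlag")
    tab = _tables(cfg)
    values, names = [], []
    for mname, dsq in zip(tab.matrix_names, tab.dist_sq):
        values.append(_coupling_numbers(idx, cfg.nlag, dsq))
        names.extend(f"{mname}.lag{d}" for d in range(1, cfg.nlag + 1))
    return FeatureVector("SOCNumber", tuple(names), np.concatenate(values))


def encode_qsorder(p: Peptide | str, cfg: EncoderConfig = EncoderConfig()) -> FeatureVector:
    """Quasi-sequence-order (2·(20 + nlag) components).

    Per distance matrix: 20 residue-frequency components followed by nlag
    coupling components, all sharing the denominator Σf_r + w Στ_d, so each
    block sums to 1. Blocks ordered Schneider–Wrede-style then Grantham.
    """
    idx = _indices(p)
    _check_lag(idx, cfg.nlag, "nlag")
    tab = _tables(cfg)
    freqs = _counts(idx) / len(idx)
    values, names = [], []
    for mname, dsq in zip(tab.matrix_names, tab.dist_sq):
        tau = _coupling_numbers(idx, cfg.nlag, dsq)
        denom = freqs.sum() + cfg.w_qsorder * tau.sum()
        values.append(np.concatenate([freqs, cfg.w_qsorder * tau]) / denom)
        names.extend(f"{mname}.{r}" for r in STANDARD_RESIDUES)
        names.extend(f"{mname}.lag{d}" for d in range(1, cfg.nlag + 1))
    return FeatureVector("QSOrder", tuple(names), np.concatenate(values))


_ENCODER_FUNCS = {
    "AAC": lambda p, cfg: encode_aac(p),
    "TPAAC": encode_tpaac,
    "APAAC": encode_apaac,
    "ASDC": lambda p, cfg: encode_asdc(p),
    "DPC": lambda p, cfg: encode_dpc(p),
    "DDE": lambda p, cfg: encode_dde(p),
    "GAAC": lambda p, cfg: encode_gaac(p),
    "GDPC": lambda p, cfg: encode_gdpc(p),
    "SOCNumber": encode_socnumber,
    "QSOrder": encode_qsorder,
}


def encode_all(
    p: Peptide | str, cfg: EncoderConfig = EncoderConfig()
) -> list[FeatureVector]:
    """Apply the ten encoders in the fixed order (1,337 components at defaults)."""
    return [_ENCODER_FUNCS[name](p, cfg) for name in ENCODER_ORDER]


class PeptideEncoder(TransformerMixin, BaseEstimator):
    """Transform peptide sequences into a descriptor feature matrix.

    A stateless scikit-learn transformer: ``fit`` only validates the
    configuration and freezes the output column names; ``transform`` maps an
    iterable of sequences (or :class:`Peptide`) to a dense array whose
    columns follow the fixed encoder order. At the defaults (all ten
    encoders, λ = nlag = 1) the output has 1,337 columns.

    Parameters
    ----------
    encoders : "all" or sequence of encoder names
        Subset of :data:`ENCODER_ORDER` to apply (order is always the fixed
        canonical one regardless of the order given).
    lambda_, nlag : int
        Maximum correlation lags; every encoded peptide must be longer.
    omega_tpaac, w_apaac, w_qsorder : float
        Weighting factors of the pseudo-composition and quasi-sequence-order
        descriptors.
    """

    def __init__(
        self,
        encoders: str | tuple[str, ...] = "all",
        lambda_: int = 1,
        omega_tpaac: float = 0.05,
        w_apaac: float = 0.5,
        w_qsorder: float = 0.1,
        nlag: int = 1,
    ):
        self.encoders = encoders
        self.lambda_ = lambda_
        self.omega_tpaac = omega_tpaac
        self.w_apaac = w_apaac
        self.w_qsorder = w_qsorder
        self.nlag = nlag

    def _config(self) -> EncoderConfig:
        return EncoderConfig(
            lambda_=self.lambda_,
            omega_tpaac=self.omega_tpaac,
            w_apaac=self.w_apaac,
            w_qsorder=self.w_qsorder,
            nlag=self.nlag,
        )

    def _encoder_names(self) -> tuple[str, ...]:
        if self.encoders == "all":
            return ENCODER_ORDER
        names = (
            (self.encoders,) if isinstance(self.encoders, str) else tuple(self.encoders)
        )
        unknown = set(names) - set(ENCODER_ORDER)
        if unknown:
            raise ValueError(f"unknown encoders: {sorted(unknown)}")
        return tuple(e for e in ENCODER_ORDER if e in names)

    def fit(self, X=None, y=None) -> "PeptideEncoder":
        cfg = self._config()
        probe = "A" * (max(cfg.lambda_, cfg.nlag) + 1)
        names: list[str] = []
        for enc in self._encoder_names():
            names.extend(_ENCODER_FUNCS[enc](probe, cfg).qualified_names)
        self.feature_names_out_ = np.array(names, dtype=object)
        self.n_features_out_ = len(names)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        cfg = self._config()
        enc_names = self._encoder_names()
        rows = []
        for p in X:
            vecs = [_ENCODER_FUNCS[e](p, cfg) for e in enc_names]
            rows.append(np.concatenate([v.values for v in vecs]))
        if not rows:
            return np.empty((0, self.n_features_out_))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        return self.feature_names_out_
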