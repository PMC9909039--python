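"""Descriptor fusion and zero-column removal.

The ten per-encoder vectors are concatenated in the fixed encoder order
into one fused vector (1,337 columns at the default λ = nlag = 1). Columns
that are identically zero in the fitting matrix carry no discriminative
signal and are removed; the retained column set is recorded in a
:class:`FusionSchema` so that train-time and prediction-time matrices stay
column-consistent. By default the filter is fitted on the training
partition only; fitting on the full dataset is available for comparison.
Constant-but-nonzero columns are kept.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .encoders import ENCODER_ORDER, EncoderConfig, PeptideEncoder
from .peptides import LabeledDataset

__all__ = ["FusionSchema", "ZeroColumnFilter", "fuse", "fit_zero_filter", "apply_schema"]


@dataclass(frozen=True)
class FusionSchema:
    """Record of the fused column order and the columns kept after
    zero-column removal, tied to the matrix it was fitted on."""

    encoder_order: tuple[str, ...]
    kept_columns: tuple[str, ...]
    fitted_on: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "encoder_order": list(self.encoder_order),
                    "kept_columns": list(self.kept_columns),
                    "fitted_on": self.fitted_on,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionSchema":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["encoder_order"]), tuple(d["kept_columns"]), d["fitted_on"]
        )


def _matrix_hash(m: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(map(str, m.columns)).encode())
    h.update(np.ascontiguousarray(m.to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


def fuse(
    dataset: LabeledDataset, cfg: EncoderConfig = EncoderConfig()
) -> pd.DataFrame:
    """Encode every peptide with all ten encoders and fuse the vectors.

    Returns a DataFrame indexed by peptide id with qualified column names
    (``encoder.component``); labels, when present, are attached as
    ``df.attrs["labels"]``. Encoding failures abort with the peptide id.
    """
    enc = PeptideEncoder(
        lambda_=cfg.lambda_,
        omega_tpaac=cfg.omega_tpaac,
        w_apaac=cfg.w_apaac,
        w_qsorder=cfg.w_qsorder,
        nlag=cfg.nlag,
    ).fit()
    rows = []
    for p in dataset:
        try:
            rows.append(enc.transform([p])[0])
        except ValueError as exc:
            raise ValueError(f"cannot encode peptide {p.id!r}: {exc}") from exc
    mat = np.vstack(rows) if rows else np.empty((0, enc.n_features_out_))
    df = pd.DataFrame(mat, index=dataset.ids, columns=enc.feature_names_out_)
    if all(p.label is not None for p in dataset) and len(dataset):
        df.attrs["labels"] = np.array([p.label for p in dataset], dtype=int)
    return df


class ZeroColumnFilter(TransformerMixin, BaseEstimator):
    """Remove feature columns that are identically zero in the fitting data.

    ``fit`` records the support mask and (when the input is a DataFrame)
    the kept column names; ``transform`` selects exactly those columns, in
    fit order, even if they happen to be all-zero in the new data. A
    fitted filter exports/imports a :class:`FusionSchema`.
    """

    def fit(self, X, y=None) -> "ZeroColumnFilter":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.array(X.columns, dtype=object)
            arr = X.to_numpy(float)
        else:
            self.feature_names_in_ = None
            arr = np.asarray(X, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot fit a zero-column filter on an empty matrix")
        self.n_features_in_ = arr.shape[1]
        self.support_ = (arr != 0.0).any(axis=0)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            if self.feature_names_in_ is not None:
                missing = set(self.feature_names_in_) - set(X.columns)
                if missing:
                    raise ValueError(
                        f"schema mismatch: columns missing {sorted(missing)[:5]}"
                    )
                kept = [
                    c for c, keep in zip(self.feature_names_in_, self.support_) if keep
                ]
                out = X.loc[:, kept]
                out.attrs = dict(X.attrs)
                return out
            X = X.to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"schema mismatch: expected {self.n_features_in_} columns, "
                f"got {X.shape[1]}"
            )
        return X[:, self.support_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        names = (
            self.feature_names_in_
            if input_features is None
            else np.asarray(input_features, dtype=object)
        )
        if names is None:
            names = np.array(
                [f"x{i}" for i in range(self.n_features_in_)], dtype=object
            )
        return names[self.support_]

    def to_schema(self, fitted_on: str = "") -> FusionSchema:
        if self.feature_names_in_ is None:
            raise ValueError("schema export needs named columns (fit on a DataFrame)")
        kept = tuple(
            c for c, keep in zip(self.feature_names_in_, self.support_) if keep
        )
        return FusionSchema(ENCODER_ORDER, kept, fitted_on)


def fit_zero_filter(m: pd.DataFrame) -> FusionSchema:
    """Fit the zero-column filter on a fused matrix and return its schema."""
    filt = ZeroColumnFilter().fit(m)
    return filt.to_schema(fitted_on=_matrix_hash(m))


def apply_schema(m: pd.DataFrame, schema: FusionSchema) -> pd.DataFrame:
    """Select the schema's kept columns (in schema order) from a fused matrix."""
    missing = set(schema.kept_columns) - set(m.columns)
    if missing:
        raise ValueError(f"schema mismatch: columns missing {sorted(missing)[:5]}")
    out = m.loc[:, list(schema.kept_columns)]
    out.attrs = dict(m.attrs)
    return out
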