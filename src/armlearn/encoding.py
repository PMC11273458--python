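"""Numeric encoding of variants from per-amino-acid physicochemical properties.

A variant code over P positions is encoded as the concatenation of the
property vectors of its residues, giving a fixed-length descriptor of width
P x n_properties (5 x 25 = 125 for the default table).  Feature columns are
named ``pos<index>_<property>`` so that the (position, property) pair can be
recovered from any column name.

Standardization statistics are learned once on a training split and then
reused for every later transform, so held-out rows and screening candidates
are always expressed on the training scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .properties import raw_property_frame
from .variant_space import VariantSpace

__all__ = [
    "PropertyTable",
    "FeatureMatrix",
    "encode_variants",
    "standardize",
    "subset_features",
    "parse_feature_name",
]


class PropertyTable:
    """20 amino-acid rows x property columns, z-scored across amino acids."""

    def __init__(self, frame: pd.DataFrame, zscore: bool = True):
        if frame.isna().any().any():
            raise ValueError("property table contains missing values")
        if zscore:
            frame = (frame - frame.mean()) / frame.std(ddof=0)
        self.frame = frame

    @classmethod
    def default(cls) -> "PropertyTable":
        """The built-in curated table of 25 literature physicochemical indices."""
        return cls(raw_property_frame())

    @classmethod
    def from_csv(cls, path: str | Path, zscore: bool = True) -> "PropertyTable":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame, zscore=zscore)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)

    @property
    def properties(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_properties(self) -> int:
        return self.frame.shape[1]

    def vector(self, amino_acid: str) -> np.ndarray:
        return self.frame.loc[amino_acid].to_numpy()

    def subset(self, properties: Sequence[str]) -> "PropertyTable":
        missing = [p for p in properties if p not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown properties: {missing}")
        return PropertyTable(self.frame[list(properties)], zscore=False)


@dataclass
class FeatureMatrix:
    """Encoded variants: rows are variants, columns position x property features.

    ``center``/``scale`` hold standardization statistics once fitted; they are
    treated as immutable and reused for all later transforms.
    """

    X: np.ndarray
    columns: list[str]
    variants: list[str]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if self.X.shape[0] != len(self.variants):
            raise ValueError("row count mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def is_standardized(self) -> bool:
        return self.center is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns, index=self.variants)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("variant_code").to_csv(path)


def encode_variants(
    variants: Iterable[str],
    table: PropertyTable,
    space: VariantSpace,
) -> FeatureMatrix:
    """Encode variant codes into a FeatureMatrix over ``space.positions``."""
    variants = [space.validate_variant(v) for v in variants]
    props = table.properties
    columns = [f"pos{p}_{prop}" for p in space.positions for prop in props]
    lookup = {aa: table.vector(aa) for aa in space.alphabet}
    rows = np.empty((len(variants), len(columns)))
    for i, code in enumerate(variants):
        try:
            rows[i] = np.concatenate([lookup[aa] for aa in code])
        except KeyError as exc:
            raise KeyError(
                f"variant {code!r}: letter {exc.args[0]!r} not in property table"
            ) from exc
    return FeatureMatrix(X=rows, columns=columns, variants=variants)


def standardize(
    fm: FeatureMatrix,
    fit: bool = True,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Column-standardize a feature matrix.

    With ``fit=True`` the mean/sd are learned from ``fm`` itself (constant
    columns get sd treated as 1, mapping them to zero).  With ``fit=False``
    the previously fitted ``stats`` (center, scale) must be supplied, e.g.
    ``standardize(fm_test, fit=False, stats=(fm_train.center, fm_train.scale))``.
    """
    if fit:
        center = fm.X.mean(axis=0)
        scale = fm.X.std(axis=0, ddof=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
    else:
        if stats is None:
            raise ValueError("fit=False requires previously fitted stats")
        center, scale = (np.asarray(s, dtype=float) for s in stats)
        if center.shape != (fm.X.shape[1],) or scale.shape != (fm.X.shape[1],):
            raise ValueError("stats shape does not match feature width")
    Xs = (fm.X - center) / scale
    return FeatureMatrix(X=Xs, columns=list(fm.columns), variants=list(fm.variants), center=center, scale=scale)


def subset_features(fm: FeatureMatrix, selected: Sequence[str]) -> FeatureMatrix:
    """Select feature columns by name, in the order requested."""
    if len(set(selected)) != len(selected):
        dupes = sorted({s for s in selected if list(selected).count(s) > 1})
        raise ValueError(f"duplicate feature names requested: {dupes}")
    index = {name: i for i, name in enumerate(fm.columns)}
    missing = [s for s in selected if s not in index]
    if missing:
        raise KeyError(f"unknown feature names: {missing}")
    idx = [index[s] for s in selected]
    return FeatureMatrix(
        X=fm.X[:, idx],
        columns=list(selected),
        variants=list(fm.variants),
        center=None if fm.center is None else fm.center[idx],
        scale=None if fm.scale is None else fm.scale[idx],
    )


def parse_feature_name(name: str) -> tuple[int, str]:
    """Invert ``pos<index>_<property>`` back to (position, property)."""
    if not name.startswith("pos"):
        raise ValueError(f"not a positional feature name: {name!r}")
    head, _, prop = name.partition("_")
    return int(head[3:]), prop
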