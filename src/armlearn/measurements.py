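"""Plate normalization, log transformation and replicate-based noise estimation.

Screening data arrive as per-well raw activities in 96-well plates, each
plate carrying reference-variant ("ref") and empty-vector ("ev") controls.
Activities are expressed relative to the per-plate reference mean, so the
reference is 1.0 on every plate by construction.  Modeling happens on the
natural-log scale, where replicate scatter is approximately Gaussian with a
variance that is assumed constant across variants; the pooled replicate
standard deviation parameterizes the Gaussian-process likelihood and is NOT
re-optimized during model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REF_LABEL",
    "EV_LABEL",
    "NoiseEstimate",
    "normalize_to_reference",
    "log_transform",
    "estimate_noise",
    "summarize_ssm",
    "merge_tables",
    "training_rows",
]

REF_LABEL = "ref"
EV_LABEL = "ev"


def normalize_to_reference(raw: pd.DataFrame) -> pd.DataFrame:
    """Add per-plate reference-normalized activities.

    ``raw`` needs columns ``plate_id, well_id, label, raw_activity``; a
    ``relative_activity`` column (raw / per-plate mean of "ref" rows) is
    added.  Empty-vector rows are retained as background indicators.
    """
    required = {"plate_id", "well_id", "label", "raw_activity"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if not np.isfinite(raw["raw_activity"]).all():
        raise ValueError("raw_activity contains non-finite values")
    out = raw.copy()
    ref_means = (
        out[out["label"] == REF_LABEL].groupby("plate_id")["raw_activity"].mean()
    )
    plates = out["plate_id"].unique()
    without_ref = sorted(set(plates) - set(ref_means.index))
    if without_ref:
        raise ValueError(f"plates without a '{REF_LABEL}' control: {without_ref}")
    out["relative_activity"] = out["raw_activity"] / out["plate_id"].map(ref_means)
    return out


def log_transform(
    table: pd.DataFrame,
    floor: float = 0.01,
    column: str = "relative_activity",
) -> pd.DataFrame:
    """Add ``log_activity = ln(max(activity, floor))`` and a ``floored`` flag.

    The floor (default 1% of the reference activity) keeps inactive variants
    as informative finite observations rather than dropping them.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    out = table.copy()
    vals = out[column].to_numpy(dtype=float)
    out["floored"] = vals < floor
    out["log_activity"] = np.log(np.maximum(vals, floor))
    return out


@dataclass(frozen=True)
class NoiseEstimate:
    """Pooled standard deviation of replicate log-activity residuals."""

    sigma_log: float
    n_variants_with_replicates: int
    n_residuals: int
    method: str = "pooled"

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def estimate_noise(
    table: pd.DataFrame,
    label_column: str = "label",
    value_column: str = "log_activity",
    method: str = "pooled",
    include_controls: bool = False,
) -> NoiseEstimate:
    """Estimate measurement noise from variants observed multiple times.

    ``pooled`` (default) is the degrees-of-freedom-corrected pooled standard
    deviation  sqrt( sum_v sum_i (y_vi - mean_v)^2 / sum_v (n_v - 1) ) over
    variants v with n_v >= 2 observations.  ``plain`` divides by the number
    of residuals instead.  Control rows ("ref"/"ev") are excluded unless
    ``include_controls`` is set.
    """
    if method not in ("pooled", "plain"):
        raise ValueError(f"unknown method {method!r}")
    df = table
    if not include_controls:
        df = df[~df[label_column].isin((REF_LABEL, EV_LABEL))]
    groups = df.groupby(label_column)[value_column]
    ss = 0.0
    dof = 0
    n_res = 0
    n_var = 0
    for _, vals in groups:
        n = len(vals)
        if n < 2:
            continue
        arr = vals.to_numpy(dtype=float)
        ss += float(((arr - arr.mean()) ** 2).sum())
        dof += n - 1
        n_res += n
        n_var += 1
    if n_var == 0:
        raise ValueError(
            "no variant has >= 2 observations; supply sigma_log manually"
        )
    denom = dof if method == "pooled" else n_res
    return NoiseEstimate(
        sigma_log=float(np.sqrt(ss / denom)),
        n_variants_with_replicates=n_var,
        n_residuals=n_res,
        method=method,
    )


def summarize_ssm(
    table: pd.DataFrame,
    position_column: str = "position",
    value_column: str = "relative_activity",
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-position summary of a single-site-saturation screen.

    Returns max and mean relative activity and the count of variants above
    the reference (``n_above``) per randomized position, ranked by max
    activity — the signal used to pick positions for combinatorial
    randomization.
    """
    df = table[~table["label"].isin((REF_LABEL, EV_LABEL))] if "label" in table else table
    summary = (
        df.groupby(position_column)[value_column]
        .agg(
            max_activity="max",
            mean_activity="mean",
            n_above=lambda v: int((v > threshold).sum()),
        )
        .sort_values("max_activity", ascending=False)
        .reset_index()
    )
    return summary


def merge_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    """Concatenate measurement tables that share the reference normalization.

    Used to merge historical data (e.g. an earlier double-mutant screen) with
    new rounds after both are expressed relative to the same reference
    variant.
    """
    return pd.concat(tables, ignore_index=True)


def training_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for model training: controls removed, replicates retained."""
    return table[~table["label"].isin((REF_LABEL, EV_LABEL))].reset_index(drop=True)
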