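"""Correlation of per-condition texture means with observer AUC.

Pearson coefficients are computed per feature over three condition sets: the
unfiltered (noisy) arm, the Wiener-filtered arm, and both arms pooled.
Features whose absolute coefficient clears a threshold in all three columns
are highlighted; feature-versus-projection-number curves are classified by
the sign of their fitted quadratic curvature.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tomotex.errors import ParameterError, SchemaError
from tomotex.texture import FEATURE_NAMES

HIGHLIGHT_THRESHOLD = 0.85
#: Decimal places of the printed coefficients used for threshold comparison.
PRINTED_PRECISION = 4

ARMS = ("noisy", "filtered")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (missing) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ParameterError("pearson needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def load_reference_correlations() -> pd.DataFrame:
    """Published 13x3 coefficient matrix used by the worked-example tests."""
    with resources.files("tomotex.data").joinpath("reference_feature_auc_correlations.csv").open() as fh:
        return pd.read_csv(fh)


def correlate_conditions(
    features: pd.DataFrame,
    aucs: pd.DataFrame,
    subset: Sequence[int],
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Per-feature Pearson coefficients over the two arms and their pooled set.

    ``features`` needs columns (P, arm, <feature>_mean ...); ``aucs`` needs
    (P, arm, auc).  ``subset`` lists the projection numbers entering the
    correlation (conditions where both tables have data).
    """
    subset = list(subset)
    feat_key = features.set_index(["arm", "P"])
    auc_key = aucs.set_index(["arm", "P"])
    missing = [
        (arm, p)
        for arm in ARMS
        for p in subset
        if (arm, p) not in feat_key.index or (arm, p) not in auc_key.index
    ]
    if missing:
        raise SchemaError(f"conditions missing from feature or AUC tables: {missing}")

    rows = []
    for name in feature_names:
        col = f"{name}_mean"
        if col not in feat_key.columns:
            raise SchemaError(f"feature table lacks column {col!r}")
        per_arm = {}
        pooled_x, pooled_y = [], []
        for arm in ARMS:
            x = np.array([feat_key.loc[(arm, p), col] for p in subset], dtype=float)
            y = np.array([auc_key.loc[(arm, p), "auc"] for p in subset], dtype=float)
            per_arm[arm] = pearson(x, y)
            pooled_x.extend(x)
            pooled_y.extend(y)
        rows.append(
            {
                "feature": name,
                "r_noisy": per_arm["noisy"],
                "r_filtered": per_arm["filtered"],
                "r_combined": pearson(pooled_x, pooled_y),
            }
        )
    table = pd.DataFrame(rows)
    table["highlighted"] = table["feature"].isin(highlight_features(table))
    return table


def highlight_features(
    table: pd.DataFrame,
    threshold: float = HIGHLIGHT_THRESHOLD,
    precision: int = PRINTED_PRECISION,
) -> list:
    """Features with |r| >= threshold (at printed precision) in every column."""
    out = []
    for _, row in table.iterrows():
        rs = [row["r_noisy"], row["r_filtered"], row["r_combined"]]
        if any(pd.isna(r) for r in rs):
            continue
        if all(abs(round(float(r), precision)) >= threshold for r in rs):
            out.append(row["feature"])
    return out


def low_correlation_features(table: pd.DataFrame, threshold: float = 0.7) -> list:
    """Features with |r| below ``threshold`` in all three columns."""
    out = []
    for _, row in table.iterrows():
        rs = [row["r_noisy"], row["r_filtered"], row["r_combined"]]
        if all(pd.notna(r) and abs(float(r)) < threshold for r in rs):
            out.append(row["feature"])
    return out


def classify_concavity(
    feature_means: Sequence[float],
    p_values: Optional[Sequence[float]] = None,
    rel_tol: float = 1e-9,
) -> str:
    """Sign of the least-squares quadratic coefficient over increasing P.

    Returns "concave-up", "concave-down", or "indeterminate" when the fitted
    curvature is negligible relative to the data scale.
    """
    y = np.asarray(feature_means, dtype=float)
    if y.size < 4:
        raise ParameterError("classify_concavity needs at least 4 points")
    x = np.arange(y.size, dtype=float) if p_values is None else np.asarray(p_values, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("p_values must match feature_means in length")
    a = np.polyfit(x, y, 2)[0]
    # Curvature's contribution to the curve over the observed P range,
    # compared with the overall data scale.
    span = (x.max() - x.min()) / 2.0
    scale = max(np.abs(y).max(), np.finfo(float).tiny)
    if abs(a) * span**2 < rel_tol * scale:
        return "indeterminate"
    return "concave-up" if a > 0 else "concave-down"


def concavity_report(features: pd.DataFrame, subset: Sequence[int], arm: str = "noisy") -> dict:
    """Concavity label per feature from the per-condition mean table."""
    sub = features[features["arm"] == arm].sort_values("P")
    sub = sub[sub["P"].isin(subset)]
    return {
        name: classify_concavity(sub[f"{name}_mean"].to_numpy(float), sub["P"].to_numpy(float))
        for name in FEATURE_NAMES
    }
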