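"""Association analyses of drug therapy with disease activity.

Quartile rescaling of the DAS28-CRP subscores, Pearson chi-square tests on
drug-class-by-stage (or -quartile) contingency tables, and Kruskal-Wallis
tests of therapy timing across activity stages.  Thin, validated wrappers
around scipy; chi-square is computed without continuity correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, kruskal

__all__ = ["chi2_test", "kruskal_wallis", "quartile_rescale"]


class AssociationError(ValueError):
    """Invalid input to an association test."""


def quartile_rescale(values) -> np.ndarray:
    """Map values to quartile labels 1-4.

    Thresholds are the linear-interpolation (type-7) quantiles; label 1 for
    v <= Q1, 2 for Q1 < v <= Q2, 3 for Q2 < v <= Q3, else 4.  Ties share the
    lower label (all-equal input maps to all 1).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise AssociationError("quartile_rescale needs at least 4 values")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    labels = np.ones(v.size, dtype=int)
    labels[v > q1] = 2
    labels[v > q2] = 3
    labels[v > q3] = 4
    return labels


def chi2_test(table) -> dict:
    """Pearson chi-square of a labeled contingency table, without correction.

    Returns statistic, df = (r-1)(c-1), p and the Pearson residuals
    ``(obs - exp) / sqrt(exp)``.
    """
    t = pd.DataFrame(table)
    arr = t.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise AssociationError("contingency table must be at least 2 x 2")
    if (arr < 0).any():
        raise AssociationError("counts must be nonnegative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise AssociationError("zero row or column margin")
    chi2, p, dof, expected = chi2_contingency(arr, correction=False)
    residuals = (arr - expected) / np.sqrt(expected)
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "residuals": pd.DataFrame(residuals, index=t.index, columns=t.columns),
    }


def kruskal_wallis(*groups) -> dict:
    """Kruskal-Wallis rank test with tie correction; df = k - 1.

    All-identical observations return H = 0 (with a warning) instead of
    erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise AssociationError("kruskal_wallis needs >= 2 nonempty groups")
    if sum(g.size for g in groups) < 3:
        raise AssociationError("kruskal_wallis needs >= 3 observations in total")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical: H = 0", stacklevel=2)
        return {"H": 0.0, "df": df, "p": 1.0}
    h, p = kruskal(*groups)
    return {"H": float(h), "df": df, "p": float(p)}
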