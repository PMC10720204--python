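"""Coefficient-space PCA across exposures and profile-specificity correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signature import SignatureModel

__all__ = [
    "build_coefficient_matrix",
    "coefficient_pca",
    "specificity_correlations",
]


def build_coefficient_matrix(models: dict[str, SignatureModel]) -> pd.DataFrame:
    """Union-of-selected-metabolites x exposures matrix of mean coefficients.

    A metabolite not selected for a given exposure gets a zero entry.
    """
    rows = sorted(set().union(*(m.selected for m in models.values())))
    out = pd.DataFrame(0.0, index=pd.Index(rows, name="metabolite"),
                       columns=list(models))
    for name, model in models.items():
        for met, coef in model.mean_coef.items():
            out.loc[met, name] = coef
    return out


def coefficient_pca(matrix: pd.DataFrame):
    """PCA of the centered/scaled coefficient matrix (metabolites as rows).

    Returns (loadings, scores, variance_fractions).  Sign convention: the
    largest-magnitude entry of each loading vector is positive (PCA signs are
    otherwise arbitrary).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if np.isnan(X).any():
        raise ValueError("missing entries; apply the zero-fill rule first")
    mu = X.mean(0)
    sd = X.std(0, ddof=1)
    if (sd == 0).any():
        bad = matrix.columns[sd == 0].tolist()
        raise ValueError(f"constant columns after centering: {bad}")
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    V = Vt.T
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] *= -1
            U[:, k] *= -1
    comp = [f"PC{k + 1}" for k in range(V.shape[1])]
    loadings = pd.DataFrame(V, index=matrix.columns, columns=comp)
    scores = pd.DataFrame(U * s, index=matrix.index, columns=comp)
    return loadings, scores, frac


def specificity_correlations(
    scores: pd.DataFrame, intakes: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each signature score with each reported intake.

    Rows are signatures, columns exposures; on exposure-specific planted
    signals the diagonal should dominate.
    """
    if len(scores) != len(intakes):
        raise ValueError("scores and intakes are misaligned")
    out = pd.DataFrame(index=scores.columns, columns=intakes.columns, dtype=float)
    for s in scores.columns:
        x = scores[s].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"score {s!r} has zero variance")
        for e in intakes.columns:
            y = intakes[e].to_numpy(dtype=float)
            if np.std(y) == 0:
                raise ValueError(f"intake {e!r} has zero variance")
            out.loc[s, e] = float(np.corrcoef(x, y)[0, 1])
    return out
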