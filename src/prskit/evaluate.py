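"""Linear scoring and prediction-accuracy metrics.

A polygenic score is the dosage-weighted sum of per-allele effects.
Accuracy is reported as *incremental R²*: the variance explained by a
linear model with the PRS plus covariates, minus that of a covariates-only
model — the phenotype stays on its original scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ld_estimate import GenotypePanel

__all__ = ["EvalResult", "score", "incremental_r2", "outlier_filter"]


@dataclass(frozen=True)
class EvalResult:
    incremental_r2: float
    r2_full: float
    r2_covariates_only: float
    n_samples: int


def score(panel: GenotypePanel, fit_table: pd.DataFrame) -> np.ndarray:
    """Per-sample PRS from a fitted effect table.

    ``fit_table`` needs columns SNP, A1, A2, BETA (per-allele scale).
    Variants are matched on rsID; when the panel counts the model's A2
    instead of its A1, the effect sign is flipped (which shifts all
    scores by a constant — 2·Σβ over flipped variants — without changing
    their ranking).  Missing dosages contribute the variant's mean dosage.
    """
    model = fit_table.set_index(fit_table["SNP"].astype(str))
    panel_rsid = panel.variants["rsid"].astype(str).to_numpy()
    panel_a1 = panel.variants["a1"].astype(str).str.upper().to_numpy()
    panel_a2 = panel.variants["a2"].astype(str).str.upper().to_numpy()

    idx, weights = [], []
    for i, rsid in enumerate(panel_rsid):
        if rsid not in model.index:
            continue
        row = model.loc[rsid]
        a1, a2 = str(row["A1"]).upper(), str(row["A2"]).upper()
        b = float(row["BETA"])
        if (a1, a2) == (panel_a1[i], panel_a2[i]):
            idx.append(i)
            weights.append(b)
        elif (a1, a2) == (panel_a2[i], panel_a1[i]):
            # panel counts the other allele: dosage' = 2 - dosage
            idx.append(i)
            weights.append(-b)
    if not idx:
        raise ValueError("no variants shared between panel and fit table")
    idx = np.asarray(idx)
    weights = np.asarray(weights)
    X = panel.dosages[:, idx]
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), means, X)
    return X @ weights


def incremental_r2(prs: np.ndarray, phenotype: np.ndarray,
                   covariates: Optional[np.ndarray] = None) -> EvalResult:
    """R²(phenotype ~ PRS + covariates) − R²(phenotype ~ covariates).

    Both models are ordinary least squares with an intercept.  Invariant
    to affine rescaling of the PRS and of the covariates.
    """
    y = np.asarray(phenotype, dtype=np.float64).ravel()
    prs = np.asarray(prs, dtype=np.float64).ravel()
    n = len(y)
    if len(prs) != n:
        raise ValueError("sample mismatch between PRS and phenotype")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates do not align with samples")
    intercept = np.ones((n, 1))
    X_cov = np.hstack([intercept, C])
    X_full = np.hstack([intercept, C, prs[:, None]])
    if n < X_full.shape[1] + 2:
        raise ValueError("need at least 2 more samples than regressors")

    def r2(X):
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient design matrix in the evaluation model")
        resid = y - X @ coef
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            return 0.0
        return 1.0 - float(np.sum(resid ** 2)) / tss

    r2_cov = r2(X_cov) if C.shape[1] else 0.0
    r2_full = r2(X_full)
    return EvalResult(incremental_r2=r2_full - r2_cov, r2_full=r2_full,
                      r2_covariates_only=r2_cov, n_samples=n)


def outlier_filter(values: np.ndarray) -> np.ndarray:
    """Boolean mask keeping values within 3 SD of the mean.

    One pass only: the mean and SD are computed once on the input, not
    re-estimated after removal.  A zero-variance input passes through.
    """
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    sd = np.nanstd(x)
    if sd == 0:
        return np.ones(len(x), dtype=bool)
    return np.abs(x - np.nanmean(x)) <= 3.0 * sd
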