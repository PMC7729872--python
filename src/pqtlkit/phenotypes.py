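"""Protein-panel quality control and phenotype transformation.

The measurement model follows multiplexed antibody-based panels reported
on a natural-log scale (NPX): values below the per-protein lower limit of
detection (LOD) are unreliable and set to missing, proteins with too much
missing/censored data are dropped, and the remaining phenotypes are
adjusted for technical and demographic covariates by ordinary least
squares followed by a rank-based inverse-normal transformation of the
residuals, yielding marginally standard-normal phenotypes for the mixed
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ProteinPanel

__all__ = [
    "PreparedPhenotype",
    "censor_below_lod",
    "exclude_proteins",
    "adjust_and_transform",
    "inverse_normal",
]


@dataclass
class PreparedPhenotype:
    """Standardized residual phenotype for one protein."""

    protein: str
    values: pd.Series  # index: sample id; no missing entries
    n_used: int


def censor_below_lod(panel: ProteinPanel) -> ProteinPanel:
    """Set NPX entries strictly below the per-protein LOD to missing.

    Censored entries are flagged in ``below_lod`` rather than silently
    dropped, so downstream QC can count them.
    """
    below = panel.npx.lt(panel.lod, axis=1) & panel.npx.notna()
    npx = panel.npx.mask(below)
    return ProteinPanel(npx=npx, lod=panel.lod, plate=panel.plate, below_lod=below)


def exclude_proteins(panel: ProteinPanel, max_bad: float = 0.40) -> tuple[ProteinPanel, list]:
    """Drop proteins whose missing-or-below-LOD proportion exceeds ``max_bad``.

    The inequality is strict: a protein at exactly the threshold is kept.
    """
    if not 0.0 < max_bad < 1.0:
        raise ValueError("max_bad must be in (0, 1)")
    below = panel.below_lod if panel.below_lod is not None else panel.npx.isna() & False
    bad = (panel.npx.isna() | below).mean(axis=0)
    excluded = list(bad.index[bad > max_bad])
    if len(excluded) == len(panel.npx.columns):
        raise ValueError("all proteins excluded by the missingness/LOD filter")
    keep = [c for c in panel.npx.columns if c not in excluded]
    out = ProteinPanel(
        npx=panel.npx[keep],
        lod=panel.lod[keep],
        plate=panel.plate,
        below_lod=panel.below_lod[keep] if panel.below_lod is not None else None,
    )
    return out, excluded


def inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, quantile offset (r - 0.5) / n.

    Ties receive average ranks.  Input must be free of missing values.
    """
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def _design_matrix(cov: pd.DataFrame, mean_npx: pd.Series | None) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    age = cov["age"].to_numpy(float)
    cols += [age, age**2]
    names += ["age", "age2"]
    if "sex" in cov:
        cols.append(cov["sex"].to_numpy(float))
        names.append("sex")
    if "plate" in cov:
        plates = pd.get_dummies(cov["plate"], drop_first=True)
        for c in plates.columns:
            cols.append(plates[c].to_numpy(float))
            names.append(f"plate_{c}")
    if "season" in cov:
        cols.append((cov["season"] == "winter").to_numpy(float))
        names.append("season")
    if mean_npx is not None:
        cols.append(mean_npx.to_numpy(float))
        names.append("mean_npx")
    return np.column_stack(cols), names


def _drop_redundant(X: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Greedily drop columns that do not increase the design rank."""
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"rank-deficient design; dropped redundant columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def adjust_and_transform(
    panel: ProteinPanel,
    covariates: pd.DataFrame,
    *,
    include_mean_npx: bool = True,
) -> dict[str, PreparedPhenotype]:
    """Covariate-adjust and inverse-normalise every protein.

    Residuals from OLS on [age, age^2, sex, plate indicators, season,
    per-sample mean NPX] are mapped to normal quantiles.  Samples with
    missing age are dropped; samples missing a given protein are dropped
    for that protein only.  The per-sample mean NPX is computed across all
    assays of the (censored) panel before any protein exclusion.
    """
    cov = covariates.set_index("id") if "id" in covariates.columns else covariates
    common = panel.npx.index.intersection(cov.index)
    cov = cov.loc[common]
    has_age = cov["age"].notna()
    if (~has_age).any():
        cov = cov.loc[has_age]
    npx = panel.npx.loc[cov.index]
    if include_mean_npx and npx.shape[1] < 2:
        warnings.warn("panel has a single protein: per-sample mean NPX would be the "
                      "phenotype itself and is skipped", stacklevel=2)
        include_mean_npx = False
    mean_npx = npx.mean(axis=1) if include_mean_npx else None

    out: dict[str, PreparedPhenotype] = {}
    X_full, names = _design_matrix(cov, mean_npx)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        X_full, names = _drop_redundant(X_full, names)
    for protein in npx.columns:
        y = npx[protein]
        ok = y.notna().to_numpy()
        Xp, yp = X_full[ok], y.to_numpy(float)[ok]
        beta, *_ = np.linalg.lstsq(Xp, yp, rcond=None)
        resid = yp - Xp @ beta
        vals = inverse_normal(resid)
        out[protein] = PreparedPhenotype(
            protein=protein,
            values=pd.Series(vals, index=y.index[ok]),
            n_used=int(ok.sum()),
        )
    return out
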