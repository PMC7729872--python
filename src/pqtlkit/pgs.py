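"""Polygenic score construction, validation and disease screening.

Scores follow the clumping + p-value-thresholding recipe: variants from
the discovery scan are LD-clumped, then every combination of a p-value
threshold (log-spaced between 1e-4 and study-wide significance) and a
frequency rule (MAF >= 0.05, MAF >= 0.01, MAC >= 10) defines a weighted
allele score ``sum_j beta_j * dosage_j``.  Validation measures the
squared Pearson correlation with prepared protein phenotypes in an
independent cohort; imputed-protein disease screening runs logistic
regressions of binary outcomes on the best score per protein, with
nested-model comparison via the likelihood-ratio test and DeLong's test
for correlated AUCs, and an elastic-net selection over all scores as the
agnostic counterpart of the per-protein screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .peaks import LDSource, clump

__all__ = [
    "PGSModel",
    "fit_scores",
    "evaluate_scores",
    "cross_validate",
    "disease_screen",
    "compare_models",
    "delong_test",
    "roc_auc",
    "elastic_net_select",
]


@dataclass
class PGSModel:
    protein: str
    weights: pd.DataFrame  # id, ea, beta, freq (discovery alt-allele freq)
    p_threshold: float
    maf_rule: str
    clump_r2: float
    clump_bp: int

    @property
    def n_variants(self) -> int:
        return len(self.weights)

    def score(self, cohort) -> np.ndarray:
        """Weighted allele score; missing dosages imputed from discovery
        frequencies, variants absent from the cohort contribute their
        expected dosage (a constant shift)."""
        s = np.zeros(cohort.n_samples)
        idx = cohort.variant_index()
        alt = dict(zip(cohort.variants["id"], cohort.variants["alt"]))
        for _, w in self.weights.iterrows():
            if w["id"] in idx:
                d = cohort.dosages[:, idx[w["id"]]].copy()
                d[np.isnan(d)] = 2.0 * w["freq"]
                if alt[w["id"]] != w["ea"]:
                    d = 2.0 - d
            else:
                d = np.full(cohort.n_samples, 2.0 * w["freq"])
            s += w["beta"] * d
        return s


def default_threshold_grid(study_threshold: float = 7.45e-11, n: int = 8) -> np.ndarray:
    """Log-spaced p-value thresholds from 1e-4 down to study-wide
    significance."""
    return np.logspace(np.log10(1e-4), np.log10(study_threshold), n)


def fit_scores(
    assoc: pd.DataFrame,
    cohort,
    threshold_grid: np.ndarray | None = None,
    maf_rules=(0.05, 0.01, "MAC10"),
    clump_r2: float = 0.1,
    clump_bp: int = 1_000_000,
    protein: str = "",
    ld_source: LDSource | None = None,
) -> list[PGSModel]:
    """One PGS per (p-threshold, frequency rule) from discovery summary
    statistics; an empty weight set at a stringent threshold is a valid
    model, not an error."""
    grid = default_threshold_grid() if threshold_grid is None else np.asarray(threshold_grid)
    ld = ld_source or LDSource(cohort)
    kept = set(clump(assoc, ld, r2=clump_r2, window_bp=clump_bp, p_max=float(grid.max())))
    base = assoc[assoc["id"].isin(kept)]
    models = []
    for rule in maf_rules:
        if rule == "MAC10":
            passing = base[base["mac"] >= 10]
        else:
            passing = base[base["maf"] >= float(rule)]
        for thr in grid:
            sel = passing[passing["p"] < thr]
            freq = [ld.freq(v) if v in ld else np.nan for v in sel["id"]]
            weights = pd.DataFrame({"id": sel["id"].to_numpy(), "ea": sel["ea"].to_numpy(),
                                    "beta": sel["beta"].to_numpy(), "freq": freq})
            models.append(PGSModel(protein=protein, weights=weights, p_threshold=float(thr),
                                   maf_rule=str(rule), clump_r2=clump_r2, clump_bp=clump_bp))
    return models


def _r2(score: np.ndarray, pheno: np.ndarray) -> tuple[float, bool]:
    if np.std(score) == 0 or np.std(pheno) == 0:
        return 0.0, True
    return float(np.corrcoef(score, pheno)[0, 1] ** 2), False


def evaluate_scores(models: list[PGSModel], validation_cohort, validation_phenotypes: dict) -> pd.DataFrame:
    """Validation r2 per model; ``best`` marks the argmax per protein.

    ``validation_phenotypes`` maps protein to the prepared phenotype
    vector aligned with the validation cohort's samples.
    """
    rows = []
    for k, model in enumerate(models):
        y = np.asarray(validation_phenotypes[model.protein], dtype=float)
        s = model.score(validation_cohort)
        r2, const = _r2(s, y)
        rows.append({"model": k, "protein": model.protein, "p_threshold": model.p_threshold,
                     "maf_rule": model.maf_rule, "n_variants": model.n_variants,
                     "r2": r2, "constant_score": const})
    out = pd.DataFrame(rows)
    out["best"] = False
    for protein, grp in out.groupby("protein"):
        out.loc[grp["r2"].idxmax(), "best"] = True
    return out


def cross_validate(
    models: list[PGSModel],
    cohort,
    phenotypes: dict,
    folds: int = 5,
    repeats: int = 3,
    holdout: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated k-fold cross-validation with a held-out fraction.

    Per repeat, a ``holdout`` fraction is set aside and the remainder is
    split into ``folds``; in each fold the best (threshold, rule) model
    per protein is chosen on the training part and its r2 recorded on the
    fold and on the holdout.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    scores = {k: m.score(cohort) for k, m in enumerate(models)}
    by_protein: dict[str, list[int]] = {}
    for k, m in enumerate(models):
        by_protein.setdefault(m.protein, []).append(k)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        n_hold = int(round(holdout * n))
        hold, work = perm[:n_hold], perm[n_hold:]
        fold_ids = np.arange(work.size) % folds
        for fold in range(folds):
            test = work[fold_ids == fold]
            train = work[fold_ids != fold]
            for protein, ks in by_protein.items():
                y = np.asarray(phenotypes[protein], dtype=float)
                best_k = max(ks, key=lambda k: _r2(scores[k][train], y[train])[0])
                rows.append({
                    "repeat": rep, "fold": fold, "protein": protein,
                    "p_threshold": models[best_k].p_threshold, "maf_rule": models[best_k].maf_rule,
                    "r2_fold": _r2(scores[best_k][test], y[test])[0],
                    "r2_holdout": _r2(scores[best_k][hold], y[hold])[0],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disease screening


def disease_screen(
    scores: pd.DataFrame,
    disease_labels: pd.DataFrame,
    covariates: pd.DataFrame,
    n_proteins: int | None = None,
    n_eff_phenotypes: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Logistic screening of binary disease codes on per-protein scores.

    Each (protein, phenotype) pair is fit as ``label ~ score +
    covariates``; the Wald p of the score coefficient is compared against
    the Bonferroni threshold ``alpha / (n_proteins * n_eff_phenotypes)``.
    Fits with (quasi-)separation are flagged and excluded from the
    significance calls.
    """
    n_proteins = n_proteins or scores.shape[1]
    n_eff = n_eff_phenotypes or disease_labels.shape[1]
    threshold = alpha / (n_proteins * n_eff)
    C = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    rows = []
    for code in disease_labels.columns:
        y = disease_labels[code].to_numpy(float)
        if y.min() == y.max():
            raise ValueError(f"phenotype {code!r} has no cases or no controls")
        for protein in scores.columns:
            s = scores[protein].to_numpy(float)
            sd = s.std()
            X = np.column_stack([(s - s.mean()) / (sd if sd > 0 else 1.0), C])
            flagged = False
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                coef, se = fit.params[0], fit.bse[0]
                if not np.isfinite(se) or se > 50:
                    flagged = True
                p = float(2 * stats.norm.sf(abs(coef / se))) if not flagged else np.nan
            except Exception:
                flagged, coef, se, p = True, np.nan, np.nan, np.nan
            rows.append({"protein": protein, "phenotype": code, "coef": coef, "se": se,
                         "wald_p": p, "separation": flagged,
                         "bonferroni_pass": bool(not flagged and p < threshold)})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    return out


def roc_auc(labels: np.ndarray, score: np.ndarray) -> float:
    """AUC by pair counting via midranks (ties get half credit)."""
    labels = np.asarray(labels).astype(bool)
    ranks = stats.rankdata(score)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both cases and controls")
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(labels: np.ndarray, score: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Structural components V10 (cases) and V01 (controls)."""
    labels = np.asarray(labels).astype(bool)
    x, yv = score[labels], score[~labels]
    m, n = x.size, yv.size
    rx = stats.rankdata(np.concatenate([x, yv]))
    rx_cases, rx_controls = rx[:m], rx[m:]
    r_cases = stats.rankdata(x)
    r_controls = stats.rankdata(yv)
    auc = (rx_cases.sum() - m * (m + 1) / 2) / (m * n)
    v10 = (rx_cases - r_cases) / n
    v01 = 1.0 - (rx_controls - r_controls) / m
    return float(auc), v10, v01


def delong_test(labels: np.ndarray, score1: np.ndarray, score2: np.ndarray) -> tuple[float, float, float]:
    """Paired DeLong test for a difference in correlated AUCs.

    Returns (auc1, auc2, two-sided p).  Identical scores give p = 1.
    """
    a1, v10_1, v01_1 = _delong_components(labels, np.asarray(score1, dtype=float))
    a2, v10_2, v01_2 = _delong_components(labels, np.asarray(score2, dtype=float))
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return a1, a2, 1.0
    z = (a1 - a2) / np.sqrt(var)
    return a1, a2, float(2 * stats.norm.sf(abs(z)))


def compare_models(y: np.ndarray, X_base: np.ndarray, X_augmented: np.ndarray):
    """Nested logistic model comparison: likelihood-ratio test plus
    DeLong's test on the fitted probabilities.

    ``X_base`` columns must all appear in ``X_augmented``.  Returns
    ``(lrt_p, auc_base, auc_augmented, delong_p)``.
    """
    Xb = np.column_stack([np.ones(len(y)), np.asarray(X_base, dtype=float)])
    Xa = np.column_stack([np.ones(len(y)), np.asarray(X_augmented, dtype=float)])
    for j in range(Xb.shape[1]):
        if not any(np.allclose(Xb[:, j], Xa[:, k]) for k in range(Xa.shape[1])):
            raise ValueError("models are not nested: a base column is absent from the augmented design")
    fb = sm.Logit(y, Xb).fit(disp=0, maxiter=200)
    fa = sm.Logit(y, Xa).fit(disp=0, maxiter=200)
    df = Xa.shape[1] - Xb.shape[1]
    lrt = 2.0 * (fa.llf - fb.llf)
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df=max(df, 1)))
    auc_b, auc_a, delong_p = delong_test(y, fb.predict(Xb), fa.predict(Xa))
    return lrt_p, auc_b, auc_a, delong_p


# ---------------------------------------------------------------------------
# elastic net score selection


def elastic_net_select(
    all_scores: pd.DataFrame,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha_grid=tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    folds: int = 10,
    holdout: float = 0.2,
    seed: int = 0,
    n_lambda: int = 25,
) -> pd.DataFrame:
    """Penalized logistic selection of informative protein scores.

    For each mixing parameter alpha (0 = ridge ... 1 = lasso) the penalty
    strength lambda is tuned by k-fold cross-validated log-loss and set
    one standard deviation above the minimising value to increase
    shrinkage; scores with nonzero coefficients at that (alpha, lambda)
    are selected, and the holdout AUC of the refit model is reported per
    alpha.  Scores are standardized; covariates enter the penalized
    design as well.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels).astype(int)
    S = all_scores.to_numpy(float)
    S = (S - S.mean(axis=0)) / np.where(S.std(axis=0) == 0, 1.0, S.std(axis=0))
    X = S if covariates is None else np.column_stack([S, covariates.to_numpy(float)])
    n = len(y)
    perm = rng.permutation(n)
    n_hold = int(round(holdout * n))
    hold, train = perm[:n_hold], perm[n_hold:]
    Xt, yt = X[train], y[train]

    resid = yt - yt.mean()
    lam_max = np.abs(Xt.T @ resid).max() / len(yt)
    lambdas = np.logspace(np.log10(lam_max * 1.2), np.log10(lam_max * 1e-3), n_lambda)

    def _fit(alpha, lam, Xf, yf):
        C = 1.0 / (len(yf) * lam)
        clf = LogisticRegression(l1_ratio=alpha, C=C, solver="saga", max_iter=5000, tol=1e-4)
        clf.fit(Xf, yf)
        return clf

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    splits = list(skf.split(Xt, yt))
    rows = []
    for alpha in alpha_grid:
        losses = np.zeros((folds, len(lambdas)))
        for fi, (tr, te) in enumerate(splits):
            for li, lam in enumerate(lambdas):
                clf = _fit(alpha, lam, Xt[tr], yt[tr])
                p = np.clip(clf.predict_proba(Xt[te])[:, 1], 1e-12, 1 - 1e-12)
                losses[fi, li] = -np.mean(yt[te] * np.log(p) + (1 - yt[te]) * np.log(1 - p))
        mean_loss = losses.mean(axis=0)
        sd_loss = losses.std(axis=0, ddof=1) / np.sqrt(folds)
        li_min = int(np.argmin(mean_loss))
        bound = mean_loss[li_min] + sd_loss[li_min]
        li_1sd = int(np.flatnonzero(mean_loss <= bound)[0])  # lambdas descend: first = strongest
        clf = _fit(alpha, lambdas[li_1sd], Xt, yt)
        coefs = clf.coef_.ravel()[: S.shape[1]]
        selected = [all_scores.columns[j] for j in np.flatnonzero(np.abs(coefs) > 1e-8)]
        auc = roc_auc(y[hold], clf.predict_proba(X[hold])[:, 1]) if n_hold else np.nan
        rows.append({"alpha": float(alpha), "lambda": float(lambdas[li_1sd]),
                     "selected": selected, "n_selected": len(selected), "holdout_auc": auc})
    return pd.DataFrame(rows)
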