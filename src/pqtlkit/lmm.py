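"""Linear mixed model association machinery.

The model is ``y = W a + u + e`` with ``u ~ N(0, sg2 K)`` and
``e ~ N(0, se2 I)``, where ``K`` is an empirical genetic relationship
matrix (GRM) built on LD-pruned common variants that pass a
Hardy-Weinberg exact test.  Variance components are estimated once per
trait by REML over the variance ratio via the GRM eigendecomposition;
per-variant association then uses the score test (chi-square with one
degree of freedom, upper tail) with effect sizes from the equivalent
generalized-least-squares fit.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "GRM",
    "VarianceComponents",
    "hwe_exact_test",
    "ld_prune",
    "compute_grm",
    "reml_fit",
    "score_scan",
    "genomic_control",
    "CHI2_MEDIAN",
]

CHI2_MEDIAN = 0.4549  # reference median of chi2(1), fixed constant

ASSOC_COLUMNS = ["chrom", "pos", "id", "ea", "oa", "maf", "mac", "miss", "beta", "se", "p", "n"]


@dataclass
class GRM:
    matrix: np.ndarray
    n_variants_used: int
    samples: list

    def __post_init__(self):
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    lambda_ratio: float
    loglik_reml: float
    eigvals: np.ndarray = field(repr=False)
    eigvecs: np.ndarray = field(repr=False)
    covariates: np.ndarray = field(repr=False)
    note: str = ""

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    def decorrelating_weights(self) -> np.ndarray:
        """1/sqrt of the eigenvalues of Sigma = sg2 K + se2 I."""
        d = self.sigma_g2 * self.eigvals + self.sigma_e2
        return 1.0 / np.sqrt(np.maximum(d, 1e-12))


# ---------------------------------------------------------------------------
# variant QC


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the allele counts, the p-value is the sum of the
    probabilities of all heterozygote counts no more probable than the
    observed one (heterozygote excess and deficit both contribute).
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative with positive sum")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    het = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - het) // 2
    hom_major = n - het - hom_minor
    logp = (
        gammaln(n + 1) - gammaln(hom_minor + 1) - gammaln(het + 1) - gammaln(hom_major + 1)
        + het * np.log(2.0)
        + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1) - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = min(n_Aa, n_minor)
    p_obs = prob[het == obs][0]
    return float(min(prob[prob <= p_obs * (1 + 1e-12)].sum(), 1.0))


def _standardized_dosages(cohort) -> np.ndarray:
    d = cohort.dosage_imputed()
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return d / sd


def ld_prune(cohort, r2_max: float, window_bp: int) -> list:
    """Greedy positional LD pruning: keep a variant unless it exceeds
    ``r2_max`` squared correlation with an already-kept variant within
    ``window_bp``.  Returns kept variant ids in position order."""
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0, 1)")
    X = _standardized_dosages(cohort)
    n = X.shape[0]
    kept: list[int] = []
    kept_pos: list[int] = []
    ids = cohort.variants["id"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    chroms = cohort.variants["chrom"].to_numpy()
    out = []
    last_chrom = None
    for j in np.lexsort((pos, chroms)):
        if chroms[j] != last_chrom:
            kept, kept_pos = [], []
            last_chrom = chroms[j]
        lo = bisect.bisect_left(kept_pos, pos[j] - window_bp)
        cand = kept[lo:]
        if cand:
            r = X[:, cand].T @ X[:, j] / n
            if np.any(r**2 > r2_max):
                continue
        kept.append(j)
        kept_pos.append(pos[j])
        out.append(ids[j])
    return out


def compute_grm(
    cohort,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    prune_r2: float = 0.2,
    prune_window_bp: int = 1_000_000,
) -> GRM:
    """GRM on the LD-pruned set of variants with MAF > ``maf_min`` passing
    the Hardy-Weinberg exact test at ``hwe_p_min``.

    K = (1/m) sum_j g_j g_j' with g_j the dosage centred at 2 f_j and
    scaled by sqrt(2 f_j (1 - f_j)).
    """
    maf = cohort.maf()
    d = cohort.dosages
    pass_qc = maf > maf_min
    for j in np.flatnonzero(pass_qc):
        col = d[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 2).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        if hwe_exact_test(n_AA, n_Aa, n_aa) < hwe_p_min:
            pass_qc[j] = False
    if not pass_qc.any():
        raise ValueError("no variants pass the GRM QC filters")
    sub = _subset_cohort(cohort, np.flatnonzero(pass_qc))
    kept_ids = set(ld_prune(sub, prune_r2, prune_window_bp))
    idx = np.flatnonzero(cohort.variants["id"].isin(kept_ids).to_numpy())
    f = cohort.alt_freq()[idx]
    X = cohort.dosage_imputed()[:, idx]
    X = (X - 2 * f) / np.sqrt(2 * f * (1 - f))
    K = X @ X.T / len(idx)
    return GRM(matrix=K, n_variants_used=len(idx), samples=list(cohort.samples["id"]))


def _subset_cohort(cohort, variant_idx: np.ndarray):
    from .simulate import Cohort

    return Cohort(
        dosages=cohort.dosages[:, variant_idx],
        variants=cohort.variants.iloc[variant_idx].reset_index(drop=True),
        samples=cohort.samples,
        kinship_truth=cohort.kinship_truth,
    )


# ---------------------------------------------------------------------------
# REML


def reml_fit(y: np.ndarray, covariates: np.ndarray | None, grm: GRM) -> VarianceComponents:
    """REML estimation of (sigma_g2, sigma_e2) via 1-D optimisation.

    The restricted likelihood is profiled over lambda = sg2/se2 using the
    GRM eigendecomposition; a decade grid on log10(lambda) in [-5, 5]
    brackets the optimum before Brent refinement.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    W = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    K = grm.matrix
    vals, U = np.linalg.eigh(K)
    if vals.min() < -1e-4 * max(1.0, vals.max()):
        raise ValueError(f"GRM is not positive semi-definite (min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    yt = U.T @ y
    Wt = U.T @ W
    c = W.shape[1]

    def neg_loglik(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        d = lam * vals + 1.0
        WtD = Wt / d[:, None]
        A = Wt.T @ WtD
        Ainv_Wty = np.linalg.solve(A, WtD.T @ yt)
        yPy = yt @ (yt / d) - (WtD.T @ yt) @ Ainv_Wty
        sign, logdetA = np.linalg.slogdet(A)
        return 0.5 * (np.sum(np.log(d)) + logdetA + (n - c) * np.log(max(yPy, 1e-300)))

    grid = np.linspace(-5, 5, 21)
    vals_grid = [neg_loglik(g) for g in grid]
    i = int(np.argmin(vals_grid))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_loglik, bounds=(lo, hi), method="bounded")
    log10_lam = res.x if res.fun < vals_grid[i] else grid[i]
    lam = 10.0**log10_lam

    d = lam * vals + 1.0
    WtD = Wt / d[:, None]
    A = Wt.T @ WtD
    yPy = yt @ (yt / d) - (WtD.T @ yt) @ np.linalg.solve(A, WtD.T @ yt)
    se2 = yPy / (n - c)
    sg2 = lam * se2
    note = ""
    if np.allclose(K, np.eye(n), atol=1e-10):
        note = "GRM is the identity: sg2 and se2 are not separately identifiable"
    if log10_lam <= -4.9:
        sg2, lam = 0.0, 0.0
        se2 = yPy / (n - c)
    return VarianceComponents(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        lambda_ratio=float(lam),
        loglik_reml=float(-neg_loglik(np.log10(lam) if lam > 0 else -5.0)),
        eigvals=vals,
        eigvecs=U,
        covariates=W,
        note=note,
    )


# ---------------------------------------------------------------------------
# score scan


def _decorrelate(vc: VarianceComponents, M: np.ndarray) -> np.ndarray:
    w = vc.decorrelating_weights()
    return (vc.eigvecs.T @ M) * (w[:, None] if M.ndim == 2 else w)


def _project_out(W: np.ndarray, M: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(W, M, rcond=None)
    return M - W @ coef


def score_scan(
    y_prepared: np.ndarray,
    cohort,
    vc: VarianceComponents,
    mac_min: int = 10,
    miss_max: float = 0.01,
) -> pd.DataFrame:
    """Genome-wide single-variant mixed-model score test.

    Variants with minor allele count below ``mac_min`` or missingness
    above ``miss_max`` are excluded; missing dosages are mean-imputed.
    Effect sizes (per alt allele, phenotype-SD units) and standard errors
    come from the generalized-least-squares fit under the fitted variance
    components; the p-value is the chi-square(1) upper tail of the score
    statistic.  Zero-variance variants after filtering are skipped.
    """
    keep = (cohort.mac() >= mac_min) & (cohort.missingness() <= miss_max)
    idx = np.flatnonzero(keep)
    G = cohort.dosage_imputed()[:, idx]
    y = np.asarray(y_prepared, dtype=float)

    ys = _decorrelate(vc, y)
    Gs = _decorrelate(vc, G)
    Ws = _decorrelate(vc, vc.covariates)
    yr = _project_out(Ws, ys)
    Gr = _project_out(Ws, Gs)

    denom = np.einsum("ij,ij->j", Gr, Gr)
    ok = denom > 1e-10
    num = Gr.T @ yr
    beta = np.where(ok, num / np.where(ok, denom, 1.0), np.nan)
    se = np.where(ok, 1.0 / np.sqrt(np.where(ok, denom, 1.0)), np.nan)
    chi2 = np.where(ok, (num**2) / np.where(ok, denom, 1.0), np.nan)
    p = stats.chi2.sf(chi2, df=1)

    v = cohort.variants.iloc[idx]
    out = pd.DataFrame(
        {
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "id": v["id"].to_numpy(),
            "ea": v["alt"].to_numpy(),
            "oa": v["ref"].to_numpy(),
            "maf": cohort.maf()[idx],
            "mac": cohort.mac()[idx],
            "miss": cohort.missingness()[idx],
            "beta": beta,
            "se": se,
            "p": np.clip(p, 1e-300, 1.0),
            "n": np.sum(~np.isnan(cohort.dosages[:, idx]), axis=0),
        }
    )
    return out[ok].reset_index(drop=True)


def genomic_control(assoc: pd.DataFrame, lo: float = 0.97, hi: float = 1.05) -> tuple[float, bool]:
    """Genomic-control inflation factor and the per-trait QC gate.

    lambda_GC = median(chi2) / 0.4549; the trait passes when the factor
    lies in [lo, hi].
    """
    if len(assoc) < 100:
        raise ValueError("need >= 100 variants to estimate lambda_GC")
    chi2 = stats.chi2.isf(assoc["p"].to_numpy(), df=1)
    lam = float(np.median(chi2) / CHI2_MEDIAN)
    return lam, bool(lo <= lam <= hi)
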