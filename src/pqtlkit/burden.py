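"""Gene-based rare-variant burden testing under the linear mixed model.

For each gene, four functional masks are built from variant annotation:

* ``severe``        - coding variants with a consequence strictly more
                      severe than missense, unit weights;
* ``coding_cadd``   - all coding variants, weighted by CADD phred;
* ``exon_reg_eigen``- coding plus gene-linked regulatory variants,
                      weighted by Eigen phred;
* ``reg_only_eigen``- gene-linked regulatory variants only, Eigen phred.

All masks apply a MAF < 5% and missingness < 1% filter.  Testing uses the
optimal unified burden/variance-component statistic (SKAT-O): the score
vector is computed on mixed-model-decorrelated residuals, the statistic
``Q_rho = (1 - rho) * sum w_j^2 S_j^2 + rho * (sum w_j S_j)^2`` is
evaluated on a rho grid, per-rho p-values come from the distribution of a
quadratic form in normals (characteristic-function inversion, with
moment-matching fallback) and the overall p-value from the
minimum-p one-dimensional integration of the SKAT-O construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import quadform
from .lmm import VarianceComponents, _decorrelate, _project_out

__all__ = [
    "SEVERITY_RANK",
    "BurdenMask",
    "BurdenResult",
    "build_masks",
    "SkatOKernel",
    "skato_lmm",
    "conditional_burden",
    "burden_meta",
    "DEFAULT_RHO_GRID",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

# consequence severity, higher = more severe; "severe" masks take rank > missense
SEVERITY_RANK = {
    "splice_acceptor": 10,
    "splice_donor": 10,
    "stop_gained": 9,
    "frameshift": 9,
    "stop_lost": 8,
    "start_lost": 8,
    "missense": 5,
    "splice_region": 4,
    "synonymous": 3,
    "utr": 2,
    "regulatory": 1,
    "intronic": 0,
    "intergenic": 0,
}
CODING_CLASSES = {c for c, r in SEVERITY_RANK.items() if r >= 3}
MISSENSE_RANK = SEVERITY_RANK["missense"]


@dataclass
class BurdenMask:
    gene: str
    scheme: str
    variant_ids: list
    weights: np.ndarray

    def __post_init__(self):
        if len(self.variant_ids) != len(self.weights):
            raise ValueError("weights must align with variant_ids")
        if np.any(np.asarray(self.weights) < 0):
            raise ValueError("weights must be non-negative")


@dataclass
class BurdenResult:
    gene: str
    scheme: str
    Q: float
    rho_opt: float
    p: float
    n_variants: int
    cum_mac: int
    n_samples: int
    p_conditional: float | None = None
    note: str = ""


def build_masks(
    gene: str,
    annotation: pd.DataFrame,
    cohort,
    maf_max: float = 0.05,
    miss_max: float = 0.01,
    include_missense: bool = False,
) -> list[BurdenMask]:
    """Build the four functional masks for one gene (some may be empty)."""
    ann = annotation.set_index("id")
    linked = ann["gene_links"].fillna("").str.split(",").apply(lambda l: gene in l)
    if not linked.any():
        raise KeyError(f"gene {gene!r} has no linked variants in the annotation")
    maf = pd.Series(cohort.maf(), index=cohort.variants["id"])
    miss = pd.Series(cohort.missingness(), index=cohort.variants["id"])
    ok = (maf < maf_max) & (maf > 0) & (miss < miss_max)
    rare_linked = [v for v in ann.index[linked] if v in ok.index and ok[v]]

    def _mask(scheme, member_filter, weight_col):
        ids = [v for v in rare_linked if member_filter(ann.loc[v])]
        if weight_col is None:
            w = np.ones(len(ids))
        else:
            w = ann.loc[ids, weight_col].to_numpy(float) if ids else np.array([])
        return BurdenMask(gene=gene, scheme=scheme, variant_ids=ids, weights=w)

    min_severe = MISSENSE_RANK if include_missense else MISSENSE_RANK + 1
    return [
        _mask("severe", lambda a: SEVERITY_RANK.get(a["consequence"], 0) >= min_severe
              and a["consequence"] in CODING_CLASSES, None),
        _mask("coding_cadd", lambda a: a["consequence"] in CODING_CLASSES, "cadd_phred"),
        _mask("exon_reg_eigen", lambda a: a["consequence"] in CODING_CLASSES or a["consequence"] == "regulatory",
              "eigen_phred"),
        _mask("reg_only_eigen", lambda a: a["consequence"] == "regulatory", "eigen_phred"),
    ]


# ---------------------------------------------------------------------------
# SKAT-O kernel


class SkatOKernel:
    """Cached SKAT-O test for one mask under one set of variance components.

    The genotype matrix is decorrelated with the mixed-model covariance,
    covariates are projected out, functional weights are folded into the
    column scale, and all mixture eigen-structures needed for per-rho and
    omnibus p-values are precomputed so that many phenotypes (for example
    null replicates) can be tested cheaply.
    """

    def __init__(
        self,
        G: np.ndarray,
        weights: np.ndarray,
        vc: VarianceComponents | None,
        rho_grid=DEFAULT_RHO_GRID,
        extra_covariates: np.ndarray | None = None,
        n_null: int = 100_000,
        null_seed: int = 12345,
    ):
        G = np.asarray(G, dtype=float)
        n, m = G.shape
        if m == 0:
            raise ValueError("empty mask")
        self.rho_grid = tuple(rho_grid)
        self.vc = vc
        if vc is not None:
            Gs = _decorrelate(vc, G)
            W = vc.covariates
            if extra_covariates is not None:
                W = np.column_stack([W, extra_covariates])
            Ws = _decorrelate(vc, W)
        else:
            Gs = G
            W = np.ones((n, 1))
            if extra_covariates is not None:
                W = np.column_stack([W, extra_covariates])
            Ws = W
        self._Ws = Ws
        self._c = Ws.shape[1]
        Z = _project_out(Ws, Gs) * np.asarray(weights, dtype=float)[None, :]
        self._Z = Z
        self.m = m
        self.n = n

        ZtZ = Z.T @ Z
        self._lam_rho = []
        self._liu_rho = []
        for rho in self.rho_grid:
            a = np.sqrt(1.0 - rho)
            b = (np.sqrt(1.0 - rho + m * rho) - a) / m
            M = a * np.eye(m) + b * np.ones((m, m))
            lam = np.linalg.eigvalsh(M @ ZtZ @ M)
            lam = lam[lam > 1e-10 * max(lam.max(), 1.0)]
            self._lam_rho.append(lam)
            self._liu_rho.append(quadform.liu_params(lam))

        # decomposition along the mean genotype direction for the deep-tail
        # integration route of the omnibus step
        zbar = Z.mean(axis=1)
        zz = float(zbar @ zbar)
        self._degenerate = zz < 1e-12 or m == 1
        if not self._degenerate:
            cvec = Z.T @ zbar
            self._tau = np.array(
                [m**2 * rho * zz + (1.0 - rho) * float(cvec @ cvec) / zz for rho in self.rho_grid]
            )
            Zc = Z - np.outer(zbar, cvec) / zz
            lam_k = np.linalg.eigvalsh(Zc.T @ Zc)
            lam_k = lam_k[lam_k > 1e-10 * max(lam_k.max(), 1.0)]
            self._lam_kappa = lam_k
            self._liu_kappa = quadform.liu_params(lam_k)
            avec = Zc @ cvec
            self._mu_q = lam_k.sum()
            var_remain = 4.0 * float(avec @ avec) / zz
            self._var_q = 2.0 * (lam_k**2).sum() + var_remain
            self._var_core = 2.0 * (lam_k**2).sum()
        # exact-null Monte Carlo for the omnibus: under H0 the weighted score
        # vector is N(0, Z'Z) exactly, so the null distribution of the
        # minimum per-rho p (the SKAT-O statistic) can be sampled directly
        self._n_null = n_null
        self._null_seed = null_seed
        self._null_Q_sorted: np.ndarray | None = None
        self._null_T_sorted: np.ndarray | None = None
        scale = max(float(np.abs(ZtZ).max()), 1.0)
        self._chol = np.linalg.cholesky(ZtZ + 1e-10 * scale * np.eye(m))

    def _null_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Null samples of Q_rho (sorted per rho) and of the statistic T.

        Per-rho marginals are uniformised by their own empirical ranks, so
        the null law of T = min_rho p_rho depends only on the copula of
        the Q_rho, with no distributional approximation.
        """
        if self._null_T_sorted is None:
            rng = np.random.default_rng(self._null_seed)
            B = self._n_null
            n_rho = len(self.rho_grid)
            Qn = np.empty((n_rho, B))
            chunk = max(1024, int(4e6 // max(self.m, 1)))
            for s in range(0, B, chunk):
                b = min(chunk, B - s)
                S = self._chol @ rng.standard_normal((self.m, b))
                Qn[:, s : s + b] = self._q_stats(S)
            Qs = np.sort(Qn, axis=1)
            P = np.empty_like(Qn)
            for i in range(n_rho):
                P[i] = 1.0 - (np.searchsorted(Qs[i], Qn[i], side="left") + 0.5) / B
            self._null_Q_sorted = Qs
            self._null_T_sorted = np.sort(P.min(axis=0))
        return self._null_Q_sorted, self._null_T_sorted

    def _empirical_T(self, Q: np.ndarray) -> np.ndarray:
        """Minimum per-rho empirical p for observed Q columns."""
        Qs, _ = self._null_tables()
        P = np.empty_like(Q)
        for i in range(Q.shape[0]):
            P[i] = 1.0 - (np.searchsorted(Qs[i], Q[i], side="left") + 0.5) / Qs.shape[1]
        return P.min(axis=0)

    # -- score vectors ------------------------------------------------------

    def _scores(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Weighted score vectors and residual scale for each phenotype column."""
        Y = np.asarray(Y, dtype=float)
        one_d = Y.ndim == 1
        if one_d:
            Y = Y[:, None]
        Ys = _decorrelate(self.vc, Y) if self.vc is not None else Y
        R = _project_out(self._Ws, Ys)
        sigma = np.sqrt(np.einsum("ij,ij->j", R, R) / (self.n - self._c))
        S = self._Z.T @ (R / sigma[None, :])
        return S, sigma

    def _q_stats(self, S: np.ndarray) -> np.ndarray:
        """Q_rho for each rho (rows) and phenotype (columns)."""
        ssq = np.einsum("ij,ij->j", S, S)
        ssum = S.sum(axis=0)
        rho = np.asarray(self.rho_grid)[:, None]
        return (1.0 - rho) * ssq[None, :] + rho * ssum[None, :] ** 2

    # -- p-values -----------------------------------------------------------

    def _per_rho_p(self, Q: np.ndarray, exact: bool) -> np.ndarray:
        """Per-rho p-values; ``exact`` uses CF inversion, else moment matching."""
        n_rho, n_ph = Q.shape
        P = np.empty_like(Q)
        for i in range(n_rho):
            if exact:
                for j in range(n_ph):
                    P[i, j], _ = quadform.quadform_sf(Q[i, j], self._lam_rho[i])
            else:
                P[i] = quadform.liu_sf(Q[i], params=self._liu_rho[i])
        return np.clip(P, 1e-300, 1.0)

    _GL_NODES = 128
    _MC_MIN_HITS = 50  # below this many null exceedances, switch to integration

    def _omnibus_p_mc(self, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Omnibus p by rank of the empirical statistic T in the exact-null
        Monte Carlo sample.

        Returns ``(p, reliable)`` where unreliable entries (too few null
        exceedances to resolve the tail) should use the integration route.
        """
        _, Tn = self._null_tables()
        T = self._empirical_T(Q)
        hits = np.searchsorted(Tn, T, side="right")
        p = (hits + 1.0) / (Tn.size + 1.0)
        return p, hits >= self._MC_MIN_HITS

    def _omnibus_p_integration(self, T: np.ndarray) -> np.ndarray:
        """SKAT-O omnibus p from the per-phenotype minimum per-rho p ``T``.

        One-dimensional integration over the chi2(1) component shared by
        all rho values; the conditional distribution of the remaining
        mixture uses moment matching with a variance adjustment for the
        neglected cross term.  Slightly conservative; used for tails
        beyond Monte Carlo resolution.
        """
        T = np.atleast_1d(np.asarray(T, dtype=float))
        n_rho = len(self.rho_grid)
        if self._degenerate:
            return np.clip(T, None, 1.0)
        # per-rho quantiles at level T
        qmin = np.empty((n_rho, T.size))
        for i in range(n_rho):
            qmin[i] = quadform.liu_ppf(T, params=self._liu_rho[i])
        x, w = np.polynomial.legendre.leggauss(self._GL_NODES)
        x = 0.5 * (x + 1.0) * 40.0  # map to (0, 40)
        w = w * 20.0
        one_minus = np.maximum(1.0 - np.asarray(self.rho_grid), 1e-3)
        # (rho, node, pheno)
        qk = (qmin[:, None, :] - self._tau[:, None, None] * x[None, :, None]) / one_minus[:, None, None]
        kappa_q = qk.min(axis=0)
        # variance adjustment: rescale around the mean to drop the cross-term variance
        adj = np.sqrt(self._var_core / self._var_q)
        kappa_q = (kappa_q - self._mu_q) * adj + self._mu_q
        F = 1.0 - quadform.liu_sf(kappa_q, params=self._liu_kappa)
        F[kappa_q <= 0] = 0.0
        integrand = F * stats.chi2.pdf(x, 1)[:, None]
        p = 1.0 - np.einsum("i,ij->j", w, integrand)
        # the omnibus p is sandwiched between the per-rho minimum and its
        # Bonferroni bound; clip numerical overshoot into that interval
        return np.clip(p, T, np.minimum(T * n_rho, 1.0))

    def test(self, y: np.ndarray, exact: bool = True) -> tuple[float, float, float, str]:
        """Full SKAT-O test of one phenotype.

        Per-rho p-values use characteristic-function inversion; the
        omnibus p comes from the exact-null Monte Carlo of the minimum
        per-rho p, falling back to the one-dimensional integration when
        the observed statistic lies beyond Monte Carlo resolution.
        Returns ``(Q_at_rho_opt, rho_opt, p, note)``.
        """
        S, _ = self._scores(y)
        Q = self._q_stats(S)
        if self.m == 1:
            lam = self._lam_rho[0]
            p, how = quadform.quadform_sf(Q[0, 0], lam)
            return float(Q[0, 0]), float(self.rho_grid[0]), p, how
        P = self._per_rho_p(Q, exact=exact)
        i_opt = int(np.argmin(P[:, 0]))
        if len(self.rho_grid) == 1:
            return float(Q[0, 0]), float(self.rho_grid[0]), float(P[0, 0]), ""
        p_mc, reliable = self._omnibus_p_mc(Q)
        if reliable[0]:
            return float(Q[i_opt, 0]), float(self.rho_grid[i_opt]), float(p_mc[0]), "mc"
        T = P.min(axis=0)
        p = float(self._omnibus_p_integration(T)[0])
        return float(Q[i_opt, 0]), float(self.rho_grid[i_opt]), p, "integration"

    def null_pvalues(self, Y: np.ndarray) -> np.ndarray:
        """Vectorised SKAT-O p-values for many phenotype columns.

        Uses the moment-matching route per rho and the Monte Carlo
        omnibus; intended for large null simulations (multiple-testing
        calibration, type-I error checks).
        """
        S, _ = self._scores(Y)
        Q = self._q_stats(S)
        if self.m == 1 or len(self.rho_grid) == 1:
            return np.asarray(quadform.liu_sf(Q[0], params=self._liu_rho[0]))
        p, reliable = self._omnibus_p_mc(Q)
        if not reliable.all():
            deep = ~reliable
            T_liu = self._per_rho_p(Q[:, deep], exact=False).min(axis=0)
            p[deep] = self._omnibus_p_integration(T_liu)
        return p


def _mask_genotypes(mask: BurdenMask, cohort) -> np.ndarray:
    idx = cohort.variant_index()
    js = [idx[v] for v in mask.variant_ids]
    return cohort.dosage_imputed()[:, js]


def skato_lmm(
    y_prepared: np.ndarray,
    mask: BurdenMask,
    cohort,
    vc: VarianceComponents | None,
    rho_grid=DEFAULT_RHO_GRID,
) -> BurdenResult:
    """SKAT-O burden test of one mask under the fitted mixed model."""
    if len(mask.variant_ids) == 0:
        raise ValueError(f"mask {mask.gene}/{mask.scheme} is empty")
    G = _mask_genotypes(mask, cohort)
    kern = SkatOKernel(G, mask.weights, vc, rho_grid=rho_grid)
    Q, rho_opt, p, note = kern.test(np.asarray(y_prepared, dtype=float))
    macs = pd.Series(cohort.mac(), index=cohort.variants["id"])
    return BurdenResult(
        gene=mask.gene,
        scheme=mask.scheme,
        Q=Q,
        rho_opt=rho_opt,
        p=p,
        n_variants=len(mask.variant_ids),
        cum_mac=int(macs[mask.variant_ids].sum()),
        n_samples=cohort.n_samples,
        note=note,
    )


def conditional_burden(
    y_prepared: np.ndarray,
    mask: BurdenMask,
    top_variant_id: str,
    cohort,
    vc: VarianceComponents | None,
    rho_grid=DEFAULT_RHO_GRID,
) -> BurdenResult:
    """Re-test the burden conditional on its top single-point variant.

    The top variant's dosage enters the fixed effects and the burden is
    re-tested on the remaining members, so that only signals supported by
    at least two distinct variants stay significant.  A single-variant
    mask has no conditional p-value.
    """
    if top_variant_id not in mask.variant_ids:
        raise ValueError(f"{top_variant_id} is not a member of mask {mask.gene}/{mask.scheme}")
    base = skato_lmm(y_prepared, mask, cohort, vc, rho_grid=rho_grid)
    if len(mask.variant_ids) == 1:
        base.p_conditional = None
        base.note = (base.note + "; " if base.note else "") + "single-variant mask: conditional p undefined"
        return base
    keep = [v for v in mask.variant_ids if v != top_variant_id]
    wkeep = np.asarray([w for v, w in zip(mask.variant_ids, mask.weights) if v != top_variant_id])
    idx = cohort.variant_index()
    top = cohort.dosage_imputed()[:, [idx[top_variant_id]]]
    G = cohort.dosage_imputed()[:, [idx[v] for v in keep]]
    kern = SkatOKernel(G, wkeep, vc, rho_grid=rho_grid, extra_covariates=top)
    _, _, p_cond, _ = kern.test(np.asarray(y_prepared, dtype=float))
    base.p_conditional = p_cond
    return base


def burden_meta(results_cohort1: list[BurdenResult], results_cohort2: list[BurdenResult]) -> pd.DataFrame:
    """Combine per-gene/scheme burden p-values across cohorts.

    Stouffer's method on one-sided Z-equivalents weighted by sqrt(n).  A
    gene/scheme present in only one cohort keeps its single-cohort p with
    a flag instead of a meta p.
    """
    key = lambda r: (r.gene, r.scheme)
    d1 = {key(r): r for r in results_cohort1}
    d2 = {key(r): r for r in results_cohort2}
    rows = []
    for k in sorted(set(d1) | set(d2)):
        r1, r2 = d1.get(k), d2.get(k)
        if r1 is not None and r2 is not None:
            z = np.array([stats.norm.isf(min(r.p, 1 - 1e-16)) for r in (r1, r2)])
            wts = np.sqrt([r1.n_samples, r2.n_samples])
            z_meta = float(wts @ z / np.sqrt((wts**2).sum()))
            rows.append({"gene": k[0], "scheme": k[1], "p_meta": float(stats.norm.sf(z_meta)),
                         "single_cohort_only": False})
        else:
            r = r1 or r2
            rows.append({"gene": k[0], "scheme": k[1], "p_meta": r.p, "single_cohort_only": True})
    return pd.DataFrame(rows)
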