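"""Multiple-testing calibration, replication and allele-frequency drift.

Covers the study-design statistics around the association scans: the
effective number of correlated protein traits from the eigenvalue
variance of their correlation matrix, a simulation-based effective test
count when single-variant and burden results are reported together,
significance thresholds, Benjamini-Hochberg FDR, replication assessment
with LD proxies, and allele-frequency divergence of an isolate against a
reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import simulate
from .burden import SkatOKernel, build_masks
from .peaks import LDSource

__all__ = [
    "MeffReport",
    "effective_traits",
    "study_threshold",
    "bh_fdr",
    "proportion_test_one_sided",
    "InflationConfig",
    "InflationReport",
    "combined_test_inflation",
    "ReplicationReport",
    "replication_assess",
    "af_divergence",
]


@dataclass
class MeffReport:
    M: int
    eigenvalues: np.ndarray
    V_lambda_obs: float
    M_eff: float
    M_eff_rounded: int


def effective_traits(trait_corr: np.ndarray) -> MeffReport:
    """Effective number of independent traits.

    ``M_eff = M * (1 - (M - 1) * V_lambda / M^2)`` where ``V_lambda`` is
    the population variance of the eigenvalues of the trait correlation
    matrix.  Fully correlated traits count once; independent traits count
    fully.
    """
    C = np.asarray(trait_corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    M = C.shape[0]
    lam = np.linalg.eigvalsh(C)
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise ValueError(f"correlation matrix is not positive semi-definite (min eig {lam.min():.3g})")
    V = float(np.var(lam))  # population variance
    m_eff = M * (1.0 - (M - 1) * V / M**2)
    return MeffReport(M=M, eigenvalues=lam[::-1], V_lambda_obs=V, M_eff=float(m_eff),
                      M_eff_rounded=int(round(m_eff)))


def study_threshold(alpha: float, m_eff_traits: float, n_eff_variants: float) -> float:
    """Study-wide significance threshold alpha / (M_eff * n_eff_variants)."""
    if min(alpha, m_eff_traits, n_eff_variants) <= 0:
        raise ValueError("all inputs must be positive")
    return alpha / (m_eff_traits * n_eff_variants)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def proportion_test_one_sided(k: int, n: int, p0: float = 0.5) -> float:
    """One-sided one-sample proportion test (normal approximation,
    no continuity correction): upper tail of (k/n - p0)/sqrt(p0(1-p0)/n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    z = (k / n - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# combined single-point + burden effective-test simulation


@dataclass
class InflationConfig:
    """Null-simulation layout for the combined effective-test count.

    Defaults are the desk-scale study conditions: 500 samples, about
    20,000 LD-structured variants, 100 genes with all four burden masks,
    and 200 null phenotype replicates scored at alpha = 0.05.
    """

    n: int = 500
    n_blocks: int = 400
    vars_per_block: int = 50
    n_genes: int = 100
    n_replicates: int = 200
    alpha: float = 0.05
    mac_min: int = 10
    include_burden: bool = True


@dataclass
class InflationReport:
    eff_single: float
    eff_burden: float
    eff_combined: float
    ratio: float
    n_single_tests: int
    n_burden_tests: int
    config: InflationConfig


def _effective_tests(min_p: np.ndarray, alpha: float) -> float:
    q = float(np.quantile(min_p, alpha))
    return alpha / max(q, 1e-300)


def combined_test_inflation(config: InflationConfig | None = None, seed: int = 0) -> InflationReport:
    """Effective number of tests when single-point and burden results are
    reported together, from null phenotype replicates.

    For each replicate the minimum p across (a) the single-variant scan,
    (b) the gene-based SKAT-O scan, and (c) both is recorded; the
    effective test count is ``alpha`` divided by the empirical
    alpha-quantile of the minimum p, and the reported ratio is
    combined / single-point.
    """
    cfg = config or InflationConfig()
    if cfg.n_replicates < 100:
        raise ValueError("need >= 100 replicates to estimate the alpha-quantile")
    rng = np.random.default_rng(seed)
    pool = simulate.simulate_haplotypes(
        n_founder=max(cfg.n, 300), n_blocks=cfg.n_blocks, vars_per_block=cfg.vars_per_block,
        seed=int(rng.integers(2**31 - 1)),
    )
    cohort = simulate.simulate_cohort(pool, n=cfg.n, seed=int(rng.integers(2**31 - 1)))
    genes = simulate.default_gene_windows(pool, cfg.n_genes)
    ann = simulate.simulate_annotations(cohort, genes, seed=int(rng.integers(2**31 - 1)))

    Y = rng.standard_normal((cfg.n, cfg.n_replicates))

    # single-point: standardized-dosage score statistics are chi-square(1)
    keep = cohort.mac() >= cfg.mac_min
    X = cohort.dosage_imputed()[:, keep]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    X /= np.where(sd == 0, 1.0, sd)
    Yc = Y - Y.mean(axis=0)
    ysd = Yc.std(axis=0)
    chi2 = (X.T @ (Yc / ysd)) ** 2 / cfg.n
    p_single = stats.chi2.sf(chi2, df=1)
    minp_single = p_single.min(axis=0)
    n_single = int(keep.sum())

    minp_burden = np.ones(cfg.n_replicates)
    n_burden = 0
    if cfg.include_burden:
        for gene in genes["gene"]:
            for mask in build_masks(gene, ann, cohort):
                if len(mask.variant_ids) < 1:
                    continue
                kern = SkatOKernel(_gene_G(cohort, mask), mask.weights, vc=None, n_null=20_000)
                minp_burden = np.minimum(minp_burden, kern.null_pvalues(Y))
                n_burden += 1

    minp_combined = np.minimum(minp_single, minp_burden)
    eff_single = _effective_tests(minp_single, cfg.alpha)
    eff_burden = _effective_tests(minp_burden, cfg.alpha) if n_burden else 0.0
    eff_combined = _effective_tests(minp_combined, cfg.alpha) if cfg.include_burden else eff_single
    return InflationReport(
        eff_single=eff_single,
        eff_burden=eff_burden,
        eff_combined=eff_combined,
        ratio=eff_combined / eff_single,
        n_single_tests=n_single,
        n_burden_tests=n_burden,
        config=cfg,
    )


def _gene_G(cohort, mask):
    idx = cohort.variant_index()
    return cohort.dosage_imputed()[:, [idx[v] for v in mask.variant_ids]]


# ---------------------------------------------------------------------------
# replication


@dataclass
class ReplicationReport:
    table: pd.DataFrame
    n_replicated: int
    n_assessable: int
    threshold: float

    @property
    def replication_rate(self) -> float:
        return self.n_replicated / self.n_assessable if self.n_assessable else np.nan


def replication_assess(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    ld_source: LDSource,
    n_for_threshold: int,
    alpha: float = 0.05,
    tag_r2: float = 0.8,
    require_direction: bool = True,
) -> ReplicationReport:
    """Assess replication of discovery variants in an independent cohort.

    Each discovery variant maps to itself when present in the replication
    summary statistics, otherwise to its best LD proxy at r2 >
    ``tag_r2``; variants with neither (including those monomorphic in the
    replication cohort) are unassessable.  Replication requires
    ``p < alpha / n_for_threshold`` (strict) and, by default, an effect
    direction consistent with discovery (via the LD sign for proxies).
    """
    threshold = alpha / n_for_threshold
    rep = replication.set_index("id", drop=False)
    rep_ids = [i for i in rep.index]
    rows = []
    n_rep = n_ass = 0
    for _, row in discovery.iterrows():
        vid = row["id"]
        proxy, r = (vid, 1.0) if vid in rep.index else ld_source.best_tag(vid, rep_ids, r2_min=tag_r2)
        if proxy is None:
            rows.append({"id": vid, "proxy": None, "r2": np.nan, "p_replication": np.nan,
                         "assessable": False, "replicated": False})
            continue
        p_rep = float(rep.loc[proxy, "p"])
        direction_ok = True
        if require_direction:
            expected = np.sign(row["beta"]) * np.sign(r)
            direction_ok = np.sign(rep.loc[proxy, "beta"]) == expected
        replicated = bool(p_rep < threshold and direction_ok)
        n_ass += 1
        n_rep += replicated
        rows.append({"id": vid, "proxy": proxy, "r2": r**2, "p_replication": p_rep,
                     "assessable": True, "replicated": replicated})
    return ReplicationReport(table=pd.DataFrame(rows), n_replicated=n_rep, n_assessable=n_ass,
                             threshold=threshold)


# ---------------------------------------------------------------------------
# allele-frequency divergence


def af_divergence(
    cohort_maf: np.ndarray,
    ref_maf: np.ndarray,
    n_cohort: int,
    n_ref: int,
    fold_flag: float = 5.0,
) -> pd.DataFrame:
    """Per-variant frequency fold change and two-proportion z-test.

    ``fold = cohort MAF / reference MAF`` (undefined and flagged when the
    reference frequency is zero); the p-value compares allele counts in
    ``2 n`` chromosomes per cohort.  ``fold_gt_flag`` marks variants with
    more than a ``fold_flag``-fold increase in the cohort.
    """
    pc = np.asarray(cohort_maf, dtype=float)
    pr = np.asarray(ref_maf, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(pr > 0, pc / pr, np.nan)
    pool = (2 * n_cohort * pc + 2 * n_ref * pr) / (2 * n_cohort + 2 * n_ref)
    var = pool * (1 - pool) * (1 / (2 * n_cohort) + 1 / (2 * n_ref))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (pc - pr) / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "cohort_maf": pc,
            "ref_maf": pr,
            "fold": fold,
            "p": p,
            "significant": p < 0.05,
            "fold_gt_flag": np.where(np.isnan(fold), False, fold > fold_flag),
            "ref_zero": pr == 0,
        }
    )
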