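"""Synthetic cohort generator.

Emulates, at desk scale, the data structure of a whole-genome-sequenced
isolated-population proteomics study: LD-structured genotypes across the
full allele-frequency spectrum, cryptic relatedness through sib pairs,
allele-frequency drift relative to a mainland reference panel, multiplexed
protein panels on a natural-log (NPX-like) scale with per-protein lower
limits of detection, functional variant annotations with gene links, and
an independent outcome GWAS for two-sample Mendelian randomization.

The LD model is blockwise haplotype copying: every block carries a small
set of founder haplotypes and each sampled chromosome is a mosaic of them
with a per-site template-switch probability, so pairwise r-squared decays
with distance within a block and is zero in expectation across blocks.
Isolate drift perturbs reference allele frequencies with a
Balding-Nichols Beta distribution with variance ``F * p * (1 - p)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypePool",
    "Cohort",
    "EffectConfig",
    "ProteinPanel",
    "simulate_haplotypes",
    "simulate_cohort",
    "simulate_proteins",
    "simulate_outcome_gwas",
    "simulate_annotations",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# containers


@dataclass
class HaplotypePool:
    """Founder haplotypes with block structure and reference frequencies."""

    haplotypes: np.ndarray  # (2 * n_founder, m) in {0, 1}
    block_map: np.ndarray  # (m,) block id per variant
    ref_freq: np.ndarray  # (m,) alt-allele frequency in the reference panel
    pos: np.ndarray  # (m,) 1-based positions, strictly increasing
    chrom: str = "1"
    ref: np.ndarray | None = None  # (m,) reference alleles
    alt: np.ndarray | None = None

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class Cohort:
    """Diploid dosages plus variant, sample and pedigree-truth metadata.

    ``dosages`` is float (n x m) with values {0, 1, 2} and NaN for missing
    genotypes.  Coordinates are 1-based and intervals fully closed.
    """

    dosages: np.ndarray
    variants: pd.DataFrame  # chrom, pos, id, ref, alt
    samples: pd.DataFrame  # id, age, sex, plate, season
    kinship_truth: np.ndarray | None = None

    def __post_init__(self):
        pos = self.variants["pos"].to_numpy()
        for chrom in self.variants["chrom"].unique():
            p = pos[(self.variants["chrom"] == chrom).to_numpy()]
            if np.any(np.diff(p) <= 0):
                raise ValueError("variant positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency from observed genotypes (mean dosage / 2)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def mac(self) -> np.ndarray:
        """Minor allele count among observed genotypes."""
        alt = np.nansum(self.dosages, axis=0)
        n_obs = np.sum(~np.isnan(self.dosages), axis=0)
        return np.minimum(alt, 2 * n_obs - alt).astype(int)

    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def dosage_imputed(self) -> np.ndarray:
        """Dosages with per-variant mean imputation of missing entries."""
        d = self.dosages.copy()
        mask = np.isnan(d)
        if mask.any():
            col_mean = np.where(np.all(mask, axis=0), 0.0, np.nanmean(np.where(mask, np.nan, d), axis=0))
            d[mask] = np.broadcast_to(col_mean, d.shape)[mask]
        return d

    def variant_index(self) -> dict:
        return {vid: j for j, vid in enumerate(self.variants["id"])}

    def subset_samples(self, ids) -> "Cohort":
        """Restrict to the given sample ids (in the given order)."""
        lookup = {s: i for i, s in enumerate(self.samples["id"])}
        rows = np.array([lookup[s] for s in ids])
        return Cohort(
            dosages=self.dosages[rows],
            variants=self.variants,
            samples=self.samples.iloc[rows].reset_index(drop=True),
            kinship_truth=self.kinship_truth[np.ix_(rows, rows)] if self.kinship_truth is not None else None,
        )


@dataclass
class EffectConfig:
    """Genetic and technical architecture of the simulated protein panel.

    Effect sizes are per-allele in units of phenotype standard deviation;
    the variance a variant explains is ``beta^2 * Var(dosage)``.
    ``burden_effects`` entries are ``(protein, gene, per_variant_beta,
    sign)`` and load every rare variant in the gene window with the same
    signed per-allele effect.
    """

    cis_effects: list = field(default_factory=list)  # (protein, variant_id, beta)
    trans_effects: list = field(default_factory=list)
    burden_effects: list = field(default_factory=list)  # (protein, gene, beta, sign)
    h2_poly: float = 0.0
    covariate_effects: dict = field(default_factory=dict)  # age, sex, season, plate_sd
    lod_quantile: float = 0.0
    noise_sd: float | None = None  # None: fill the remaining variance budget

    def __post_init__(self):
        if not 0.0 <= self.h2_poly < 1.0:
            raise ValueError("h2_poly must be in [0, 1)")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")


@dataclass
class ProteinPanel:
    """Samples x proteins NPX-like matrix with per-protein LOD."""

    npx: pd.DataFrame  # index: sample id, columns: protein
    lod: pd.Series  # per protein
    plate: pd.Series  # per sample
    below_lod: pd.DataFrame | None = None  # bool flags, set by censoring

    @property
    def proteins(self) -> list:
        return list(self.npx.columns)


# ---------------------------------------------------------------------------
# haplotypes


def _mosaic_copy(templates: np.ndarray, n_out: int, switch_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n_out`` haplotypes as recombinant mosaics of ``templates``."""
    n_tmpl, m = templates.shape
    switch = rng.random((n_out, m)) < switch_rate
    switch[:, 0] = True
    draws = rng.integers(0, n_tmpl, size=(n_out, m))
    # index of the most recent switch point, then gather the template drawn there
    last = np.maximum.accumulate(np.where(switch, np.arange(m)[None, :], -1), axis=1)
    tmpl = draws[np.arange(n_out)[:, None], last]
    return templates[tmpl, np.arange(m)[None, :]]


def simulate_haplotypes(
    n_founder: int = 500,
    n_blocks: int = 40,
    vars_per_block: int = 50,
    maf_spectrum_params: tuple[float, float] = (0.4, 2.0),
    seed: int = 0,
    *,
    n_ancestral: int = 12,
    switch_rate: float = 0.01,
    rare_cut: float = 0.08,
    spacing_bp: int = 2_000,
    block_gap_bp: int = 400_000,
    chrom: str = "1",
) -> HaplotypePool:
    """Generate a block-structured haplotype pool.

    Per block, ``n_ancestral`` independent ancestral haplotypes are drawn
    with site frequencies from a Beta(*maf_spectrum_params*) spectrum and
    every pool haplotype is a recombinant mosaic of them, giving
    within-block LD (of magnitude roughly 1/``n_ancestral`` for adjacent
    pairs) that decays with distance at rate ``switch_rate`` per site.
    Sites whose target frequency falls below ``rare_cut`` model young
    alleles: they are assigned directly with Bernoulli draws across the
    pool, which yields genuinely rare variants (down to MAC < 10) that
    are essentially unlinked, as expected for recent mutations.
    """
    if min(n_founder, n_blocks, vars_per_block) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_founder
    blocks = []
    for _ in range(n_blocks):
        f = rng.beta(*maf_spectrum_params, size=vars_per_block)
        anc = (rng.random((min(n_ancestral, n_hap), vars_per_block)) < np.maximum(f, rare_cut)).astype(np.int8)
        if n_hap > anc.shape[0]:
            rest = _mosaic_copy(anc, n_hap - anc.shape[0], switch_rate, rng).astype(np.int8)
            block = np.vstack([anc, rest])
        else:
            block = anc
        rare = f < rare_cut
        if rare.any():
            block[:, rare] = (rng.random((n_hap, int(rare.sum()))) < f[rare]).astype(np.int8)
        blocks.append(block)
    haps = np.hstack(blocks)
    block_map = np.repeat(np.arange(n_blocks), vars_per_block)
    block_span = vars_per_block * spacing_bp
    pos = (
        block_map * (block_span + block_gap_bp)
        + (np.arange(n_blocks * vars_per_block) % vars_per_block) * spacing_bp
        + 1
    )
    freq = haps.mean(axis=0)
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.any():
        raise ValueError("monomorphic pool: every simulated variant is fixed; "
                         "increase n_founder or soften the MAF spectrum")
    m_poly = int(poly.sum())
    ref = _BASES[rng.integers(0, 4, size=m_poly)]
    alt = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, size=m_poly)) % 4]
    return HaplotypePool(
        haplotypes=haps[:, poly],
        block_map=block_map[poly],
        ref_freq=freq[poly],
        pos=pos[poly].astype(np.int64),
        chrom=chrom,
        ref=ref,
        alt=alt,
    )


# ---------------------------------------------------------------------------
# cohort


def _drift_frequencies(ref_freq: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols perturbation: p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if F == 0.0:
        return ref_freq.copy()
    a = ref_freq * (1.0 - F) / F
    b = (1.0 - ref_freq) * (1.0 - F) / F
    return rng.beta(a, b)


def _retune_pool(haps: np.ndarray, target: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shift per-site allele frequencies of a haplotype set to ``target``.

    Entries are toggled with the minimal per-site probability needed to
    move the expectation from the current frequency to the target, which
    preserves the haplotype background (and hence most LD).
    """
    out = haps.copy()
    cur = haps.mean(axis=0)
    up = target > cur
    with np.errstate(divide="ignore", invalid="ignore"):
        p_gain = np.where(up & (cur < 1.0), (target - cur) / (1.0 - cur), 0.0)
        p_loss = np.where(~up & (cur > 0.0), (cur - target) / cur, 0.0)
    u = rng.random(haps.shape)
    out[(haps == 0) & (u < p_gain[None, :])] = 1
    out[(haps == 1) & (u < p_loss[None, :])] = 0
    return out


def simulate_cohort(
    pool: HaplotypePool,
    n: int,
    n_families: int = 0,
    drift_F: float = 0.0,
    seed: int = 0,
    *,
    miss_rate: float = 0.0,
    switch_rate: float = 0.02,
    plate_size: int = 88,
) -> Cohort:
    """Sample a diploid cohort from the pool.

    ``n_families`` families each contribute one full-sib pair (expected
    relatedness 0.5 on the GRM scale, recorded in ``kinship_truth``); the
    remaining samples are unrelated.  ``drift_F`` applies isolate drift to
    the pool's allele frequencies before sampling.  Sample covariates
    (age, sex, plate, season) are drawn here; plates follow collection
    order so plate and season are strongly correlated, as in seasonal
    field collections.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= drift_F < 1.0:
        raise ValueError("drift_F must be in [0, 1)")
    if n_families > n:
        raise ValueError("n_families cannot exceed n")
    if 2 * n_families > n:
        raise ValueError("each family contributes a sib pair: need 2 * n_families <= n")
    rng = np.random.default_rng(seed)
    m = pool.n_variants

    target = _drift_frequencies(pool.ref_freq, drift_F, rng)
    cohort_pool = _retune_pool(pool.haplotypes, target, rng) if drift_F > 0 else pool.haplotypes

    n_unrel = n - 2 * n_families
    hap_a = _mosaic_copy(cohort_pool, n_unrel, switch_rate, rng)
    hap_b = _mosaic_copy(cohort_pool, n_unrel, switch_rate, rng)
    dosages = [hap_a.astype(np.float64) + hap_b.astype(np.float64)]

    kin = np.eye(n)
    if n_families > 0:
        blocks = pool.block_map
        uniq_blocks = np.unique(blocks)
        par = _mosaic_copy(cohort_pool, 4 * n_families, switch_rate, rng)
        fam_dos = np.empty((2 * n_families, m))
        for fidx in range(n_families):
            p1 = par[4 * fidx : 4 * fidx + 2]
            p2 = par[4 * fidx + 2 : 4 * fidx + 4]
            for s in range(2):
                child = np.empty((2, m), dtype=par.dtype)
                for parent, row in ((p1, 0), (p2, 1)):
                    pick = rng.integers(0, 2, size=uniq_blocks.size)
                    child[row] = parent[pick[blocks], np.arange(m)]
                fam_dos[2 * fidx + s] = child.sum(axis=0)
            i = n_unrel + 2 * fidx
            kin[i, i + 1] = kin[i + 1, i] = 0.5
        dosages.append(fam_dos)
    dos = np.vstack(dosages)

    if miss_rate > 0:
        dos[rng.random(dos.shape) < miss_rate] = np.nan

    if pool.ref is None:
        ref = _BASES[rng.integers(0, 4, size=m)]
        alt = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, size=m)) % 4]
    else:
        ref, alt = pool.ref, pool.alt
    variants = pd.DataFrame(
        {
            "chrom": pool.chrom,
            "pos": pool.pos,
            "id": [f"rs{pool.chrom}_{p}" for p in pool.pos],
            "ref": ref,
            "alt": alt,
        }
    )
    plate = np.arange(n) // plate_size
    n_plates = max(plate.max() + 1, 1)
    season_by_plate = np.where(np.arange(n_plates) < n_plates / 2, "summer", "winter")
    season = season_by_plate[plate].copy()
    flip = rng.random(n) < 0.05  # plates straddling season boundaries
    season[flip] = np.where(season[flip] == "summer", "winter", "summer")
    samples = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "age": np.clip(rng.normal(50, 12, size=n), 18, 95).round(1),
            "sex": rng.integers(0, 2, size=n),
            "plate": plate,
            "season": season,
        }
    )
    return Cohort(dosages=dos, variants=variants, samples=samples, kinship_truth=kin)


# ---------------------------------------------------------------------------
# proteins


def _resolve_burden_members(cohort: Cohort, gene_windows: pd.DataFrame, gene: str, maf_max: float) -> np.ndarray:
    row = gene_windows.loc[gene_windows["gene"] == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} not in gene_windows")
    row = row.iloc[0]
    v = cohort.variants
    inside = (v["chrom"] == row["chrom"]) & (v["pos"] >= row["start"]) & (v["pos"] <= row["end"])
    rare = cohort.maf() < maf_max
    return np.flatnonzero(inside.to_numpy() & rare & (cohort.maf() > 0))


def simulate_proteins(
    cohort: Cohort,
    effect_config: EffectConfig,
    n_proteins: int,
    seed: int = 0,
    *,
    gene_windows: pd.DataFrame | None = None,
    burden_maf_max: float = 0.05,
    baseline: float = 5.0,
) -> tuple[ProteinPanel, pd.DataFrame]:
    """Simulate an NPX-scale protein panel plus its truth table.

    Each protein is a sum of covariate effects, per-allele variant effects,
    a polygenic term ``N(0, h2_poly * K)`` with ``K`` the pedigree kinship
    truth, and Gaussian noise filling the unit variance budget.  The
    per-protein LOD is the ``lod_quantile`` empirical quantile of the
    generated values, mimicking assay-floor censoring.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    cfg = effect_config
    vidx = cohort.variant_index()
    proteins = [f"P{k:03d}" for k in range(n_proteins)]
    pmap = {p: k for k, p in enumerate(proteins)}

    def _pcol(protein):
        if isinstance(protein, (int, np.integer)):
            return int(protein)
        return pmap[protein]

    genetic = np.zeros((n, n_proteins))
    explained = np.zeros(n_proteins)
    dos = cohort.dosage_imputed()
    truth_rows = []

    for protein, vid, beta in list(cfg.cis_effects) + list(cfg.trans_effects):
        k = _pcol(protein)
        if vid not in vidx:
            raise KeyError(f"causal variant {vid!r} not in cohort")
        j = vidx[vid]
        g = dos[:, j]
        genetic[:, k] += beta * (g - g.mean())
        var = beta**2 * g.var()
        explained[k] += var
        kind = "cis" if (protein, vid, beta) in cfg.cis_effects else "trans"
        truth_rows.append({"protein": proteins[k], "kind": kind, "target": vid, "beta": beta, "var_explained": var})

    for protein, gene, beta, sign in cfg.burden_effects:
        if gene_windows is None:
            raise ValueError("burden_effects require gene_windows")
        k = _pcol(protein)
        members = _resolve_burden_members(cohort, gene_windows, gene, burden_maf_max)
        if members.size == 0:
            raise ValueError(f"gene {gene!r} has no rare variants to load")
        b = sign * beta
        g = dos[:, members].sum(axis=1)
        genetic[:, k] += b * (g - g.mean())
        var = b**2 * g.var()
        explained[k] += var
        truth_rows.append(
            {
                "protein": proteins[k],
                "kind": "burden",
                "target": gene,
                "beta": b,
                "var_explained": var,
                "members": ",".join(cohort.variants["id"].iloc[members]),
            }
        )

    budget = explained + cfg.h2_poly
    if np.any(budget > 1.0 + 1e-9):
        raise ValueError(f"variance budget exceeds 1 for proteins {np.flatnonzero(budget > 1)}")

    poly = np.zeros((n, n_proteins))
    if cfg.h2_poly > 0:
        # infinitesimal model: many small marker effects, so the polygenic
        # term has covariance h2_poly times the realized genetic
        # relationship matrix (pedigree kinship in expectation)
        common = cohort.maf() >= 0.01
        Xs = dos[:, common]
        Xs = Xs - Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        Xs = Xs / np.where(sd == 0, 1.0, sd)
        m_poly = Xs.shape[1]
        poly = Xs @ rng.normal(0.0, np.sqrt(cfg.h2_poly / m_poly), size=(m_poly, n_proteins))

    noise_sd = cfg.noise_sd if cfg.noise_sd is not None else np.sqrt(np.maximum(1.0 - budget, 1e-4))
    noise = rng.standard_normal((n, n_proteins)) * noise_sd

    cov = np.zeros(n)
    ce = cfg.covariate_effects
    age = cohort.samples["age"].to_numpy(float)
    if ce.get("age"):
        cov = cov + ce["age"] * (age - age.mean())
    if ce.get("age2"):
        a2 = (age - age.mean()) ** 2
        cov = cov + ce["age2"] * (a2 - a2.mean())
    if ce.get("sex"):
        cov = cov + ce["sex"] * cohort.samples["sex"].to_numpy(float)
    if ce.get("season"):
        cov = cov + ce["season"] * (cohort.samples["season"] == "winter").to_numpy(float)
    plate_shift = np.zeros(n)
    if ce.get("plate_sd"):
        plates = cohort.samples["plate"].to_numpy()
        shifts = rng.normal(0.0, ce["plate_sd"], size=plates.max() + 1)
        plate_shift = shifts[plates]

    values = baseline + cov[:, None] + plate_shift[:, None] + genetic + poly + noise
    npx = pd.DataFrame(values, index=cohort.samples["id"].to_numpy(), columns=proteins)
    lod = npx.quantile(cfg.lod_quantile) if cfg.lod_quantile > 0 else pd.Series(-np.inf, index=proteins)
    lod.name = "lod"

    for k in range(n_proteins):
        h2_real = (genetic[:, k].var() + poly[:, k].var()) / values[:, k].var()
        truth_rows.append({"protein": proteins[k], "kind": "h2_realized", "target": "", "beta": np.nan,
                           "var_explained": h2_real})
    truth = pd.DataFrame(truth_rows)
    panel = ProteinPanel(npx=npx, lod=lod, plate=pd.Series(cohort.samples["plate"].to_numpy(),
                                                          index=npx.index, name="plate"))
    return panel, truth


# ---------------------------------------------------------------------------
# outcome GWAS


def simulate_outcome_gwas(
    cohort2: Cohort,
    effect_config: EffectConfig,
    causal_proteins: list,
    theta,
    seed: int = 0,
    *,
    allele_swap_frac: float = 0.0,
) -> pd.DataFrame:
    """Marginal GWAS of a liability outcome in an independent cohort.

    The outcome is ``sum_p theta_p * (genetic value of protein p) + noise``
    where genetic values are rebuilt in ``cohort2`` from the exposure
    effect configuration, so a cis instrument with exposure effect
    ``beta_exp`` has expected outcome effect ``theta * beta_exp``.
    ``allele_swap_frac`` re-expresses a random subset of rows on the other
    allele (swap ea/oa, negate beta) to exercise harmonization.
    """
    rng = np.random.default_rng(seed)
    n = cohort2.n_samples
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (len(causal_proteins),))
    vidx = cohort2.variant_index()
    dos = cohort2.dosage_imputed()

    y = rng.standard_normal(n)
    for th, protein in zip(theta, causal_proteins):
        gval = np.zeros(n)
        for p, vid, beta in list(effect_config.cis_effects) + list(effect_config.trans_effects):
            if p == protein and vid in vidx:
                g = dos[:, vidx[vid]]
                gval += beta * (g - g.mean())
        y = y + th * gval

    X = dos - dos.mean(axis=0)
    varx = X.var(axis=0)
    ok = varx > 0
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.nan)
    beta[ok] = (X[:, ok] * (y - y.mean())[:, None]).mean(axis=0)[...] / varx[ok]
    resid_var = np.maximum(y.var() - beta**2 * varx, 1e-12)
    se[ok] = np.sqrt(resid_var[ok] / (n * varx[ok]))
    z = np.where(ok, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "id": cohort2.variants["id"],
            "effect_allele": cohort2.variants["alt"],
            "other_allele": cohort2.variants["ref"],
            "beta_out": beta,
            "se_out": se,
            "p_out": np.clip(p, 1e-300, 1.0),
            "n_out": n,
        }
    )
    out = out[ok].reset_index(drop=True)
    if allele_swap_frac > 0:
        swap = rng.random(len(out)) < allele_swap_frac
        ea = out.loc[swap, "effect_allele"].copy()
        out.loc[swap, "effect_allele"] = out.loc[swap, "other_allele"].to_numpy()
        out.loc[swap, "other_allele"] = ea.to_numpy()
        out.loc[swap, "beta_out"] = -out.loc[swap, "beta_out"]
    return out


# ---------------------------------------------------------------------------
# annotations


_CODING_CLASSES = ["splice_donor", "splice_acceptor", "stop_gained", "missense", "synonymous"]
_CODING_PROBS = [0.03, 0.03, 0.04, 0.45, 0.45]
_SCORE_MEANS = {
    "splice_donor": (30.0, 6.0),
    "splice_acceptor": (30.0, 6.0),
    "stop_gained": (32.0, 6.0),
    "missense": (22.0, 5.0),
    "synonymous": (8.0, 4.0),
    "regulatory": (10.0, 5.0),
    "intergenic": (3.0, 3.0),
}


def simulate_annotations(
    cohort: Cohort,
    gene_windows: pd.DataFrame,
    seed: int = 0,
    *,
    regulatory_rate: float = 0.3,
    reg_link_bp: int = 1_000_000,
    reg_link_prob: float = 0.6,
) -> pd.DataFrame:
    """Assign consequences, deleteriousness scores and gene links.

    Coding consequences (including classes more severe than missense) only
    occur inside gene windows and link the variant to that gene; variants
    outside windows are regulatory with probability ``regulatory_rate``
    and, emulating eQTL-based regulatory linking, a regulatory variant is
    linked to each gene within ``reg_link_bp`` with probability
    ``reg_link_prob``.  Scores are CADD-like and Eigen-like phred values
    (>= 0, higher = more deleterious).
    """
    if gene_windows["gene"].duplicated().any():
        raise ValueError("duplicated gene ids in gene_windows")
    rng = np.random.default_rng(seed)
    v = cohort.variants
    consequences = np.full(len(v), "intergenic", dtype=object)
    links: list[list[str]] = [[] for _ in range(len(v))]

    for _, g in gene_windows.iterrows():
        inside = ((v["chrom"] == g["chrom"]) & (v["pos"] >= g["start"]) & (v["pos"] <= g["end"])).to_numpy()
        for j in np.flatnonzero(inside):
            consequences[j] = rng.choice(_CODING_CLASSES, p=_CODING_PROBS)
            links[j].append(g["gene"])

    outside = np.flatnonzero(consequences == "intergenic")
    is_reg = rng.random(outside.size) < regulatory_rate
    for j in outside[is_reg]:
        consequences[j] = "regulatory"
        near = gene_windows[
            (gene_windows["chrom"] == v["chrom"].iloc[j])
            & (v["pos"].iloc[j] >= gene_windows["start"] - reg_link_bp)
            & (v["pos"].iloc[j] <= gene_windows["end"] + reg_link_bp)
        ]
        for gene in near["gene"]:
            if rng.random() < reg_link_prob:
                links[j].append(gene)

    cadd = np.empty(len(v))
    eigen = np.empty(len(v))
    for j, cons in enumerate(consequences):
        mu, sd = _SCORE_MEANS[cons]
        cadd[j] = max(rng.normal(mu, sd), 0.0)
        eigen[j] = max(rng.normal(mu * 0.9, sd), 0.0)

    return pd.DataFrame(
        {
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "id": v["id"].to_numpy(),
            "consequence": consequences,
            "cadd_phred": np.round(cadd, 3),
            "eigen_phred": np.round(eigen, 3),
            "gene_links": [",".join(l) for l in links],
        }
    )


def default_gene_windows(pool: HaplotypePool, n_genes: int, *, width_frac: float = 0.6) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping gene windows on the pool's blocks."""
    blocks = np.unique(pool.block_map)
    if n_genes > blocks.size:
        raise ValueError("more genes than blocks")
    chosen = blocks[np.linspace(0, blocks.size - 1, n_genes).astype(int)]
    rows = []
    for k, b in enumerate(chosen):
        p = pool.pos[pool.block_map == b]
        span = p[-1] - p[0]
        start = int(p[0] + span * (1 - width_frac) / 2)
        rows.append({"gene": f"GENE{k:03d}", "chrom": pool.chrom, "start": start,
                     "end": int(start + span * width_frac)})
    return pd.DataFrame(rows)
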