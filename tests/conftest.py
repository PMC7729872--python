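import numpy as np
import pandas as pd
import pytest

from pqtlkit import lmm, phenotypes, simulate
from pqtlkit.simulate import Cohort


@pytest.fixture(scope="session")
def pool():
    return simulate.simulate_haplotypes(n_founder=400, n_blocks=8, vars_per_block=30, seed=101)


@pytest.fixture(scope="session")
def cohort(pool):
    return simulate.simulate_cohort(pool, n=250, n_families=20, drift_F=0.02, seed=102, miss_rate=0.002)


@pytest.fixture(scope="session")
def gene_windows(pool):
    return simulate.default_gene_windows(pool, 4)


@pytest.fixture(scope="session")
def annotation(cohort, gene_windows):
    return simulate.simulate_annotations(cohort, gene_windows, seed=103)


@pytest.fixture(scope="session")
def vc_identity():
    """Variance components for an i.i.d. model (no relatedness)."""

    def make(n):
        return lmm.VarianceComponents(
            sigma_g2=0.0,
            sigma_e2=1.0,
            lambda_ratio=0.0,
            loglik_reml=0.0,
            eigvals=np.ones(n),
            eigvecs=np.eye(n),
            covariates=np.ones((n, 1)),
        )

    return make


def make_cohort(dosages, positions=None, chrom="1", sample_prefix="S", alt=None):
    """Hand-built cohort around an explicit dosage matrix (tests only)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    ref = np.array(["A"] * m)
    alt = np.array(["G"] * m) if alt is None else np.asarray(alt)
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions), "id": [f"v{j}" for j in range(m)],
         "ref": ref, "alt": alt}
    )
    samples = pd.DataFrame(
        {"id": [f"{sample_prefix}{i:04d}" for i in range(n)],
         "age": np.full(n, 50.0), "sex": np.zeros(n, dtype=int),
         "plate": np.zeros(n, dtype=int), "season": ["summer"] * n}
    )
    return Cohort(dosages=dosages, variants=variants, samples=samples, kinship_truth=np.eye(n))


@pytest.fixture(scope="session")
def prepared_protein(cohort):
    """A prepared phenotype with one planted common cis effect."""
    maf = cohort.maf()
    j = int(np.argmax(maf))
    vid = cohort.variants["id"].iloc[j]
    cfg = simulate.EffectConfig(cis_effects=[("P000", vid, 0.6)], h2_poly=0.1)
    panel, truth = simulate.simulate_proteins(cohort, cfg, 8, seed=104)
    prep = phenotypes.adjust_and_transform(phenotypes.censor_below_lod(panel), cohort.samples)
    return {"prepared": prep, "causal_variant": vid, "truth": truth}
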