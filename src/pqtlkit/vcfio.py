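"""VCF v4.2 input/output for cohort genotype matrices (GT-only FORMAT)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import Cohort

__all__ = ["write_vcf", "read_vcf", "VcfParseError"]


class VcfParseError(ValueError):
    pass


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(cohort: Cohort, path: str) -> None:
    """Write dosages as unphased diploid GT records (missing -> ``./.``)."""
    v = cohort.variants
    samples = cohort.samples["id"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]):
            length = int(v.loc[v["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dos = cohort.dosages
        for j in range(cohort.n_variants):
            gts = "\t".join("./." if np.isnan(d) else _GT[d] for d in dos[:, j])
            row = v.iloc[j]
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str) -> Cohort:
    """Read a GT-only VCF back into a :class:`Cohort`.

    Sample covariates and kinship are not part of VCF; the returned cohort
    carries sample ids only.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise VcfParseError(f"{path}: cannot open as VCF ({exc})") from exc
    sample_ids = list(vcf.samples)
    rows, dosage_cols = [], []
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            alts = rec.ALT
            if len(alts) != 1:
                raise VcfParseError(f"{path}: record {lineno} ({rec.CHROM}:{rec.POS}): expected biallelic site")
            rows.append({"chrom": rec.CHROM, "pos": rec.POS, "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                         "ref": rec.REF, "alt": alts[0]})
            gt = np.asarray(rec.genotype.array())[:, :2]
            col = gt.sum(axis=1).astype(float)
            col[(gt < 0).any(axis=1)] = np.nan
            dosage_cols.append(col)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: parse error at record {lineno + 1}: {exc}") from exc
    if not rows:
        raise VcfParseError(f"{path}: no variant records")
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols)
    samples = pd.DataFrame({"id": sample_ids})
    return Cohort(dosages=dosages, variants=variants, samples=samples, kinship_truth=None)
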