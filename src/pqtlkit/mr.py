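"""Two-sample Mendelian randomization of protein exposures on outcomes.

Instruments are the conditionally independent pQTL variants per protein;
each is matched in the outcome GWAS by identity or by its best LD tag at
r2 > 0.8, with alleles harmonized to a common effect allele (effects are
sign-flipped on allele swaps, and ambiguous palindromic variants near
MAF 0.5 are dropped).  Causal estimates use the Wald ratio for a single
instrument and fixed-effect inverse-variance weighting of per-instrument
ratios otherwise; screening across protein-outcome pairs applies
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import bh_fdr
from .peaks import LDSource

__all__ = ["Instrument", "InstrumentSet", "MRResult", "assemble_instruments", "wald_ratio",
           "ivw", "mr_screen", "WeakInstrumentWarning"]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class Instrument:
    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    provenance: str = "direct"  # or "tag"


@dataclass
class InstrumentSet:
    protein: str
    instruments: list[Instrument] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.instruments)


@dataclass
class MRResult:
    protein: str
    outcome: str
    method: str  # "wald" or "ivw"
    estimate: float
    se: float
    p: float
    n_instruments: int
    q: float | None = None
    protective: bool = False


def _in_region(chrom, pos, regions) -> bool:
    return any(chrom == c and s <= pos <= e for c, s, e in regions)


def assemble_instruments(
    exposure: pd.DataFrame,
    outcome_gwas: pd.DataFrame,
    ld_source: LDSource,
    protein: str = "",
    pleio_exclude: list | None = None,
    tag_r2: float = 0.8,
    drop_palindromic: bool = True,
    palindromic_maf: float = 0.42,
) -> InstrumentSet:
    """Match exposure instruments into the outcome GWAS and harmonize.

    ``exposure`` needs columns id, ea, oa, beta, se (independent signals
    for one protein); ``pleio_exclude`` is a list of (chrom, start, end)
    regions around known highly pleiotropic loci whose variants never
    serve as instruments.  Unmatched variants are dropped with a note.
    """
    out = outcome_gwas.set_index("id", drop=False)
    instruments, dropped = [], []
    regions = pleio_exclude or []
    for _, row in exposure.iterrows():
        vid = row["id"]
        if vid in ld_source and _in_region(ld_source.chrom(vid), ld_source.pos(vid), regions):
            dropped.append(f"{vid}: pleiotropic locus")
            continue
        if drop_palindromic and (row["ea"], row["oa"]) in _PALINDROMIC and vid in ld_source:
            f = ld_source.freq(vid)
            if min(f, 1 - f) > palindromic_maf:
                dropped.append(f"{vid}: ambiguous palindromic variant")
                continue
        if vid in out.index:
            o = out.loc[vid]
            if {o["effect_allele"], o["other_allele"]} != {row["ea"], row["oa"]}:
                dropped.append(f"{vid}: allele mismatch")
                continue
            flip = o["effect_allele"] != row["ea"]
            instruments.append(
                Instrument(
                    variant_id=vid,
                    effect_allele=row["ea"],
                    other_allele=row["oa"],
                    beta_exp=float(row["beta"]),
                    se_exp=float(row["se"]),
                    beta_out=float(-o["beta_out"] if flip else o["beta_out"]),
                    se_out=float(o["se_out"]),
                    provenance="direct",
                )
            )
        else:
            tag, r = ld_source.best_tag(vid, [i for i in out.index if i in ld_source], r2_min=tag_r2)
            if tag is None:
                dropped.append(f"{vid}: absent from outcome GWAS, no tag at r2>{tag_r2}")
                continue
            o = out.loc[tag]
            # express the tag's outcome effect on its alt-allele dosage, then
            # carry it to the exposure variant through the sign of the LD
            # correlation between the two alt-allele dosages
            beta_out = float(o["beta_out"])
            if o["effect_allele"] != ld_source.alt(tag):
                beta_out = -beta_out
            sign = np.sign(r) if r != 0 else 1.0
            instruments.append(
                Instrument(
                    variant_id=vid,
                    effect_allele=row["ea"],
                    other_allele=row["oa"],
                    beta_exp=float(row["beta"]),
                    se_exp=float(row["se"]),
                    beta_out=sign * beta_out,
                    se_out=float(o["se_out"]),
                    provenance="tag",
                )
            )
    return InstrumentSet(protein=protein, instruments=instruments, dropped=dropped)


def _check_strength(instr: Instrument):
    if abs(instr.beta_exp) / instr.se_exp < 2:
        warnings.warn(
            f"weak instrument {instr.variant_id}: |beta_exp|/se_exp < 2",
            WeakInstrumentWarning,
            stacklevel=3,
        )


def wald_ratio(instr: Instrument, protein: str = "", outcome: str = "") -> MRResult:
    """Single-instrument causal estimate beta_out / beta_exp with
    first-order standard error se_out / |beta_exp|."""
    if instr.beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for the Wald ratio")
    _check_strength(instr)
    est = instr.beta_out / instr.beta_exp
    se = instr.se_out / abs(instr.beta_exp)
    z = est / se if se > 0 else 0.0
    return MRResult(protein=protein, outcome=outcome, method="wald", estimate=float(est),
                    se=float(se), p=float(max(2 * stats.norm.sf(abs(z)), 1e-300)), n_instruments=1)


def ivw(instrument_set: InstrumentSet, outcome: str = "") -> MRResult:
    """Fixed-effect inverse-variance weighting of per-instrument Wald ratios."""
    instruments = instrument_set.instruments
    if len(instruments) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
    for ins in instruments:
        _check_strength(ins)
    ratios = np.array([i.beta_out / i.beta_exp for i in instruments])
    ses = np.array([i.se_out / abs(i.beta_exp) for i in instruments])
    w = 1.0 / ses**2
    est = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = est / se
    return MRResult(protein=instrument_set.protein, outcome=outcome, method="ivw",
                    estimate=est, se=se, p=float(max(2 * stats.norm.sf(abs(z)), 1e-300)),
                    n_instruments=len(instruments))


def mr_screen(instrument_sets: dict, fdr: float = 0.05) -> pd.DataFrame:
    """MR across all protein-outcome pairs with BH-FDR control.

    ``instrument_sets`` maps ``(protein, outcome)`` to an
    :class:`InstrumentSet`; pairs with no usable instruments are skipped.
    The protective flag marks FDR-significant pairs where genetically
    lowered protein levels imply lower outcome risk (positive causal
    estimate of the protein on the outcome).
    """
    results = []
    for (protein, outcome), iset in instrument_sets.items():
        if len(iset) == 0:
            continue
        if len(iset) == 1:
            res = wald_ratio(iset.instruments[0], protein=protein, outcome=outcome)
        else:
            res = ivw(iset, outcome=outcome)
        results.append(res)
    if not results:
        return pd.DataFrame(columns=["protein", "outcome", "method", "estimate", "se", "p",
                                     "q", "n_instruments", "protective"])
    q = bh_fdr([r.p for r in results])
    rows = []
    for r, qi in zip(results, q):
        r.q = float(qi)
        r.protective = bool(qi < fdr and r.estimate > 0)
        rows.append(vars(r).copy())
    return pd.DataFrame(rows)
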