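"""Signal extraction and approximate conditional/joint selection.

Three summary-level post-processing steps follow the single-variant scan:

* peak extraction: greedy LD pruning of significant variants by ascending
  p-value at r2 > 0.2, then grouping of the retained variants located
  within 2 Mb of each other into signals, each indexed by its lowest-p
  member;
* LD clumping (greedy by p, removing partners with r2 above a cap inside
  a window) to limit the predictor set;
* approximate conditional and joint (COJO-style) stepwise selection that
  rebuilds the multiple-regression normal equations from marginal effect
  sizes, allele frequencies, per-variant sample sizes and an LD reference,
  here always the discovery cohort itself.

Ties in p-value are broken by genomic position (lower first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["Signal", "JointModel", "LDSource", "extract_signals", "clump", "cojo_select",
           "conditional_scan", "CojoConvergenceError"]


class CojoConvergenceError(RuntimeError):
    def __init__(self, msg, partial):
        super().__init__(msg)
        self.partial = partial


@dataclass
class Signal:
    index_variant: str
    members: list
    chrom: str
    start: int
    end: int
    index_p: float


@dataclass
class JointModel:
    variant_ids: list
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    iterations: list = field(default_factory=list)
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.variant_ids, "beta_joint": self.beta,
                             "se_joint": self.se, "p_joint": self.p})


class LDSource:
    """In-sample LD oracle over a cohort's dosages.

    Provides pairwise correlations, allele frequencies and effective
    (non-missing) sample sizes keyed by variant id.
    """

    def __init__(self, cohort):
        d = cohort.dosage_imputed()
        self._X = (d - d.mean(axis=0))
        sd = self._X.std(axis=0)
        sd[sd == 0] = 1.0
        self._Xs = self._X / sd
        self._n = cohort.n_samples
        self._freq = cohort.alt_freq()
        self._neff = np.sum(~np.isnan(cohort.dosages), axis=0)
        self._pos = cohort.variants["pos"].to_numpy()
        self._chrom = cohort.variants["chrom"].to_numpy()
        self._alt = cohort.variants["alt"].to_numpy()
        self._idx = {vid: j for j, vid in enumerate(cohort.variants["id"])}

    def __contains__(self, vid):
        return vid in self._idx

    @property
    def ids(self):
        return list(self._idx)

    def r(self, id1: str, id2: str) -> float:
        j1, j2 = self._idx[id1], self._idx[id2]
        return float(self._Xs[:, j1] @ self._Xs[:, j2] / self._n)

    def r2(self, id1: str, id2: str) -> float:
        return self.r(id1, id2) ** 2

    def r_matrix(self, ids) -> np.ndarray:
        js = [self._idx[i] for i in ids]
        X = self._Xs[:, js]
        return X.T @ X / self._n

    def freq(self, vid: str) -> float:
        return float(self._freq[self._idx[vid]])

    def neff(self, vid: str) -> int:
        return int(self._neff[self._idx[vid]])

    def pos(self, vid: str) -> int:
        return int(self._pos[self._idx[vid]])

    def chrom(self, vid: str) -> str:
        return str(self._chrom[self._idx[vid]])

    def alt(self, vid: str) -> str:
        return str(self._alt[self._idx[vid]])

    def best_tag(self, vid: str, candidates, r2_min: float = 0.8):
        """Highest-r2 tag of ``vid`` among ``candidates``; ties broken by
        distance.  Returns (tag_id, r) or (None, 0)."""
        best, best_r, best_dist = None, 0.0, None
        for c in candidates:
            if c not in self._idx or vid not in self._idx:
                continue
            r = self.r(vid, c)
            dist = abs(self.pos(vid) - self.pos(c))
            if r**2 > r2_min and (
                r**2 > best_r**2 + 1e-12
                or (abs(r**2 - best_r**2) <= 1e-12 and best_dist is not None and dist < best_dist)
            ):
                best, best_r, best_dist = c, r, dist
        return best, best_r


def _sorted_by_p(assoc: pd.DataFrame) -> pd.DataFrame:
    return assoc.sort_values(["p", "chrom", "pos"], kind="mergesort")


def extract_signals(
    assoc: pd.DataFrame,
    threshold: float,
    r2_prune: float = 0.2,
    merge_bp: int = 2_000_000,
    ld_source: LDSource | None = None,
) -> list[Signal]:
    """Peak extraction by greedy LD pruning and distance grouping.

    Significant variants are visited by increasing p; each visit removes
    all remaining variants in LD (r2 > ``r2_prune``) with the current
    one.  Retained variants within ``merge_bp`` of each other (transitive
    chaining on the same chromosome) form one signal whose index is the
    lowest-p member.
    """
    sig = _sorted_by_p(assoc[assoc["p"] < threshold])
    if sig.empty:
        return []
    retained, removed = [], set()
    pruned_members: dict[str, list] = {}
    for _, row in sig.iterrows():
        vid = row["id"]
        if vid in removed:
            continue
        retained.append(row)
        pruned_members[vid] = [vid]
        for _, other in sig.iterrows():
            ov = other["id"]
            if ov == vid or ov in removed:
                continue
            if ld_source is not None and ld_source.r2(vid, ov) > r2_prune:
                removed.add(ov)
                pruned_members[vid].append(ov)
    ret = pd.DataFrame(retained).sort_values(["chrom", "pos"])
    signals = []
    group: list = []

    def flush(group):
        if not group:
            return
        rows = pd.DataFrame(group)
        index = rows.sort_values(["p", "pos"], kind="mergesort").iloc[0]
        members = sorted({m for r in group for m in pruned_members[r["id"]]})
        signals.append(
            Signal(
                index_variant=index["id"],
                members=members,
                chrom=str(index["chrom"]),
                start=int(rows["pos"].min()),
                end=int(rows["pos"].max()),
                index_p=float(index["p"]),
            )
        )

    for _, row in ret.iterrows():
        if group and (row["chrom"] != group[-1]["chrom"] or row["pos"] - group[-1]["pos"] >= merge_bp):
            flush(group)
            group = []
        group.append(row)
    flush(group)
    signals.sort(key=lambda s: (s.chrom, s.start))
    return signals


def clump(
    assoc: pd.DataFrame,
    ld_source: LDSource,
    r2: float = 0.1,
    window_bp: int = 1_000_000,
    p_max: float = 1.0,
) -> list:
    """Greedy LD clumping: visit variants by ascending p (< ``p_max``),
    retain the current index and discard partners with squared
    correlation above ``r2`` within ``window_bp``.  Returns retained ids
    in p order."""
    cand = _sorted_by_p(assoc[assoc["p"] < p_max])
    retained, removed = [], set()
    for _, row in cand.iterrows():
        vid = row["id"]
        if vid in removed:
            continue
        retained.append(vid)
        near = cand[
            (cand["chrom"] == row["chrom"])
            & ((cand["pos"] - row["pos"]).abs() <= window_bp)
            & (cand["id"] != vid)
        ]
        for ov in near["id"]:
            if ov not in removed and ld_source.r2(vid, ov) > r2:
                removed.add(ov)
    return retained


# ---------------------------------------------------------------------------
# approximate joint / conditional algebra


def _joint_fit(ids, assoc_idx: pd.DataFrame, ld_ref: LDSource):
    """Approximate multiple regression from summary statistics.

    Normal equations use X'X ~ D^(1/2) R D^(1/2) with D_j = 2 f_j (1-f_j)
    n_j and X'y_j = D_jj b_j; the phenotype is assumed standardized
    (y'y ~ n), matching the prepared-phenotype convention.
    """
    k = len(ids)
    f = np.array([ld_ref.freq(i) for i in ids])
    nj = np.array([float(assoc_idx.loc[i, "n"]) if "n" in assoc_idx.columns else ld_ref.neff(i) for i in ids])
    b = assoc_idx.loc[ids, "beta"].to_numpy(float)
    se = assoc_idx.loc[ids, "se"].to_numpy(float)
    D = 2.0 * f * (1.0 - f) * nj
    R = ld_ref.r_matrix(ids)
    sqD = np.sqrt(D)
    B = sqD[:, None] * R * sqD[None, :]
    Xy = D * b
    bj = np.linalg.solve(B, Xy)
    yty = np.median(D * b**2 + D * se**2 * (nj - 1.0))
    nbar = float(np.median(nj))
    dof = max(nbar - k - 1.0, 1.0)
    sigma2 = max((yty - bj @ Xy) / dof, 1e-12)
    var = sigma2 * np.linalg.inv(B).diagonal()
    sej = np.sqrt(np.maximum(var, 1e-300))
    pj = stats.chi2.sf((bj / sej) ** 2, df=1)
    return bj, sej, np.clip(pj, 1e-300, 1.0)


def cojo_select(
    assoc: pd.DataFrame,
    ld_ref: LDSource,
    p_threshold: float,
    collinearity_r2: float = 0.9,
    max_iter: int = 50,
) -> JointModel:
    """Forward-backward stepwise selection on summary statistics.

    At each forward step the candidate with the smallest conditional
    p-value given the selected set enters if it passes ``p_threshold``;
    candidates correlated above ``collinearity_r2`` with the selected set
    are skipped.  After each entry the joint model is re-fit and any
    selected variant whose joint p-value exceeds the threshold is dropped
    (backward elimination).  Iterates to a fixed point.
    """
    assoc_idx = assoc.set_index("id", drop=False)
    cand_ids = [i for i in assoc_idx.index if i in ld_ref]
    if not cand_ids:
        return JointModel([], np.array([]), np.array([]), np.array([]))
    marg = assoc_idx.loc[cand_ids]
    first = _sorted_by_p(marg).iloc[0]
    if first["p"] >= p_threshold:
        return JointModel([], np.array([]), np.array([]), np.array([]), iterations=["no variant passes threshold"])
    selected = [first["id"]]
    log = [f"start: {first['id']} (p={first['p']:.3g})"]

    for it in range(max_iter):
        changed = False
        # forward step
        best_id, best_p = None, p_threshold
        for vid in cand_ids:
            if vid in selected:
                continue
            r2max = max(ld_ref.r2(vid, s) for s in selected)
            if r2max > collinearity_r2:
                continue
            try:
                bj, sej, pj = _joint_fit(selected + [vid], assoc_idx, ld_ref)
            except np.linalg.LinAlgError:
                log.append(f"skip {vid}: singular system")
                continue
            if pj[-1] < best_p:
                best_id, best_p = vid, pj[-1]
        if best_id is not None:
            selected.append(best_id)
            log.append(f"iter {it}: add {best_id} (p_cond={best_p:.3g})")
            changed = True
        # backward elimination
        while len(selected) > 1:
            bj, sej, pj = _joint_fit(selected, assoc_idx, ld_ref)
            worst = int(np.argmax(pj))
            if pj[worst] >= p_threshold:
                dropped = selected.pop(worst)
                log.append(f"iter {it}: drop {dropped} (p_joint={pj[worst]:.3g})")
                changed = True
            else:
                break
        if not changed:
            bj, sej, pj = _joint_fit(selected, assoc_idx, ld_ref)
            return JointModel(selected, bj, sej, pj, iterations=log, converged=True)
    bj, sej, pj = _joint_fit(selected, assoc_idx, ld_ref)
    partial = JointModel(selected, bj, sej, pj, iterations=log, converged=False)
    raise CojoConvergenceError(f"stepwise selection did not converge in {max_iter} iterations", partial)


def conditional_scan(assoc: pd.DataFrame, condition_ids: list, ld_ref: LDSource) -> pd.DataFrame:
    """Association statistics conditional on a fixed set of variants.

    Each remaining variant is fit jointly with the conditioning set using
    the same approximate algebra; near-perfect proxies of the
    conditioning set (r2 > 0.99) are reported with beta 0 and p 1.
    """
    assoc_idx = assoc.set_index("id", drop=False)
    missing = [c for c in condition_ids if c not in assoc_idx.index]
    if missing:
        raise KeyError(f"conditioning variants absent from assoc: {missing}")
    rows = []
    for vid in assoc_idx.index:
        if vid in condition_ids:
            continue
        row = assoc_idx.loc[vid]
        r2max = max(ld_ref.r2(vid, c) for c in condition_ids)
        if r2max > 0.99:
            beta_c, se_c, p_c = 0.0, np.inf, 1.0
        else:
            bj, sej, pj = _joint_fit(list(condition_ids) + [vid], assoc_idx, ld_ref)
            beta_c, se_c, p_c = bj[-1], sej[-1], pj[-1]
        rows.append({"chrom": row["chrom"], "pos": row["pos"], "id": vid,
                     "beta_cond": beta_c, "se_cond": se_c, "p_cond": p_c})
    return pd.DataFrame(rows)
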