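"""Two-group differentially methylated region (DMR) calling at CG sites.

The caller is fully specified (and therefore oracle-testable) rather than a
smoothing-based method: replicate counts are pooled per site, each site gets
a two-sided test of equal methylation — Fisher's exact test when the pooled
coverage is modest (total < ``deep_total``), a two-proportion normal test
otherwise — and candidate sites (site p < alpha, |difference| >= min_diff,
consistent sign) are merged into regions when separated by at most
``max_gap_bp``.  Regions are kept when they hold at least ``min_sites``
candidates, the pooled region difference still clears ``min_diff``, and the
Stouffer-combined site evidence stays below alpha.

A replicate-aware over-dispersion guard protects against inconsistent
replicates: a site where the spread (range) of per-replicate methylation
fractions within either group exceeds the between-group difference is
flagged and excluded from candidacy.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .simulate import context_class

__all__ = ["site_test", "call_dmrs", "compare_dmr_sets", "DmrCaller"]

_SITE_KEYS = ["chrom", "pos", "strand"]


@lru_cache(maxsize=1_000_000)
def _fisher_p(m_a: int, c_a: int, m_b: int, c_b: int) -> float:
    return float(
        stats.fisher_exact([[m_a, c_a - m_a], [m_b, c_b - m_b]], alternative="two-sided")[1]
    )


def _normal_p(m_a, c_a, m_b, c_b):
    m_a, c_a = np.asarray(m_a, float), np.asarray(c_a, float)
    m_b, c_b = np.asarray(m_b, float), np.asarray(c_b, float)
    pbar = (m_a + m_b) / (c_a + c_b)
    se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / c_a + 1.0 / c_b))
    diff = m_a / c_a - m_b / c_b
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def site_test(m_a, c_a, m_b, c_b, deep_total: int = 200):
    """Per-site difference of pooled proportions and two-sided p-value.

    Fisher's exact test when ``c_a + c_b < deep_total``, else the normal
    approximation.  Accepts scalars or aligned arrays of pooled counts;
    returns ``(difference, p)`` with difference = A - B.
    """
    m_a = np.atleast_1d(np.asarray(m_a, dtype=np.int64))
    c_a = np.atleast_1d(np.asarray(c_a, dtype=np.int64))
    m_b = np.atleast_1d(np.asarray(m_b, dtype=np.int64))
    c_b = np.atleast_1d(np.asarray(c_b, dtype=np.int64))
    if ((c_a <= 0) | (c_b <= 0)).any():
        raise ValueError("site_test needs coverage in both groups")
    diff = m_a / c_a - m_b / c_b
    total = c_a + c_b
    p = np.empty(len(diff))
    deep = total >= deep_total
    if deep.any():
        p[deep] = _normal_p(m_a[deep], c_a[deep], m_b[deep], c_b[deep])
    for i in np.flatnonzero(~deep):
        p[i] = _fisher_p(int(m_a[i]), int(c_a[i]), int(m_b[i]), int(c_b[i]))
    if diff.size == 1:
        return float(diff[0]), float(p[0])
    return diff, p


def _aggregate_replicates(tables: Sequence[pd.DataFrame], context: str) -> pd.DataFrame:
    frames = []
    for t in tables:
        cls = (
            t["context_class"]
            if "context_class" in t.columns
            else context_class(t["context"])
        )
        keep = (cls == context) & (t["total_count"] > 0)
        tt = t.loc[keep, _SITE_KEYS + ["mc_count", "total_count"]].copy()
        tt["frac"] = tt["mc_count"] / tt["total_count"]
        frames.append(tt)
    if not frames:
        raise ValueError("no replicate tables given")
    cat = pd.concat(frames, ignore_index=True)
    g = cat.groupby(_SITE_KEYS, observed=True)
    out = g.agg(
        m=("mc_count", "sum"),
        c=("total_count", "sum"),
        fmax=("frac", "max"),
        fmin=("frac", "min"),
        n_rep=("frac", "size"),
    )
    out["range"] = np.where(out["n_rep"] >= 2, out["fmax"] - out["fmin"], 0.0)
    return out


def _stouffer(p_values: np.ndarray) -> float:
    """One-directional Stouffer combination of same-sign two-sided p-values."""
    z = stats.norm.isf(np.clip(p_values / 2.0, 1e-300, 1.0))
    return float(2.0 * stats.norm.sf(z.sum() / np.sqrt(len(z))))


def call_dmrs(
    tables_a: Sequence[pd.DataFrame],
    tables_b: Sequence[pd.DataFrame],
    min_diff: float = 0.15,
    alpha: float = 0.05,
    max_gap_bp: int = 250,
    min_sites: int = 3,
    deep_total: int = 200,
    dispersion_guard: bool = True,
    context: str = "CG",
) -> pd.DataFrame:
    """Call DMRs between replicate groups A and B; thin functional wrapper
    over :class:`DmrCaller` — see the module docstring for the procedure."""
    caller = DmrCaller(
        min_diff=min_diff,
        alpha=alpha,
        max_gap_bp=max_gap_bp,
        min_sites=min_sites,
        deep_total=deep_total,
        dispersion_guard=dispersion_guard,
        context=context,
    )
    caller.fit((tables_a, tables_b))
    return caller.dmrs_


class DmrCaller(BaseEstimator):
    """Estimator-style DMR caller.

    Fitted attributes: ``sites_`` (per-site statistics), ``dmrs_`` (regions,
    BED-like 0-based half-open), ``summary_`` (count, total bp, mean
    absolute difference) and ``n_skipped_`` (sites covered in one group
    only).  Direction labels: ``A_hypo`` where group A is the hypomethylated
    one (difference A - B < 0), ``B_hypo`` otherwise.
    """

    def __init__(
        self,
        min_diff: float = 0.15,
        alpha: float = 0.05,
        max_gap_bp: int = 250,
        min_sites: int = 3,
        deep_total: int = 200,
        dispersion_guard: bool = True,
        context: str = "CG",
    ):
        self.min_diff = min_diff
        self.alpha = alpha
        self.max_gap_bp = max_gap_bp
        self.min_sites = min_sites
        self.deep_total = deep_total
        self.dispersion_guard = dispersion_guard
        self.context = context

    def fit(self, X, y=None):
        tables_a, tables_b = X
        agg_a = _aggregate_replicates(tables_a, self.context)
        agg_b = _aggregate_replicates(tables_b, self.context)
        sites = agg_a.join(agg_b, how="inner", lsuffix="_a", rsuffix="_b")
        self.n_skipped_ = int(len(agg_a) + len(agg_b) - 2 * len(sites))
        sites = sites.reset_index()
        if sites.empty:
            import warnings

            warnings.warn("no sites covered in both groups; empty DMR result")

        m_a = sites["m_a"].to_numpy(np.int64)
        c_a = sites["c_a"].to_numpy(np.int64)
        m_b = sites["m_b"].to_numpy(np.int64)
        c_b = sites["c_b"].to_numpy(np.int64)
        diff = m_a / np.maximum(c_a, 1) - m_b / np.maximum(c_b, 1)
        total = c_a + c_b
        dispersed = np.zeros(len(sites), dtype=bool)
        if self.dispersion_guard and len(sites):
            rng_max = np.maximum(sites["range_a"].to_numpy(), sites["range_b"].to_numpy())
            dispersed = rng_max > np.abs(diff)

        # p-values: normal approximation at deep coverage, exact Fisher where
        # the site could become a candidate (identical to testing everywhere,
        # since candidacy requires |diff| >= min_diff anyway)
        p = np.ones(len(sites))
        method = np.full(len(sites), "none", dtype=object)
        if len(sites):
            deep = total >= self.deep_total
            p[deep] = _normal_p(m_a[deep], c_a[deep], m_b[deep], c_b[deep])
            method[deep] = "normal"
            need = ~deep & (np.abs(diff) >= self.min_diff) & ~dispersed
            for i in np.flatnonzero(need):
                p[i] = _fisher_p(int(m_a[i]), int(c_a[i]), int(m_b[i]), int(c_b[i]))
            method[need] = "fisher"
            shallow_rest = ~deep & ~need
            p[shallow_rest] = _normal_p(
                m_a[shallow_rest], c_a[shallow_rest], m_b[shallow_rest], c_b[shallow_rest]
            )
            method[shallow_rest] = "normal-screen"

        sites = sites.assign(diff=diff, p=p, p_method=method, dispersed=dispersed)
        self.sites_ = sites

        cand = (
            (np.abs(diff) >= self.min_diff)
            & (p < self.alpha)
            & ~dispersed
            & (diff != 0)
        )
        cs = sites[cand].sort_values(["chrom", "pos"]).reset_index(drop=True)
        regions = []
        if len(cs):
            sign = np.sign(cs["diff"].to_numpy())
            new = np.ones(len(cs), dtype=bool)
            same_chrom = cs["chrom"].to_numpy()[1:] == cs["chrom"].to_numpy()[:-1]
            gap_ok = np.diff(cs["pos"].to_numpy()) <= self.max_gap_bp
            same_sign = sign[1:] == sign[:-1]
            new[1:] = ~(same_chrom & gap_ok & same_sign)
            rid = np.cumsum(new) - 1
            for r in np.unique(rid):
                sub = cs[rid == r]
                if len(sub) < self.min_sites:
                    continue
                sm_a, sc_a = sub["m_a"].sum(), sub["c_a"].sum()
                sm_b, sc_b = sub["m_b"].sum(), sub["c_b"].sum()
                mean_a, mean_b = sm_a / sc_a, sm_b / sc_b
                rdiff = mean_a - mean_b
                if abs(rdiff) < self.min_diff:
                    continue
                rp = _stouffer(sub["p"].to_numpy())
                if rp >= self.alpha:
                    continue
                regions.append(
                    {
                        "chrom": sub["chrom"].iloc[0],
                        "start": int(sub["pos"].min() - 1),
                        "end": int(sub["pos"].max()),
                        "n_sites": int(len(sub)),
                        "mean_a": float(mean_a),
                        "mean_b": float(mean_b),
                        "diff": float(rdiff),
                        "p": float(rp),
                        "direction": "A_hypo" if rdiff < 0 else "B_hypo",
                    }
                )
        dmrs = pd.DataFrame(
            regions,
            columns=[
                "chrom",
                "start",
                "end",
                "n_sites",
                "mean_a",
                "mean_b",
                "diff",
                "p",
                "direction",
            ],
        )
        dmrs = dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.dmrs_ = dmrs
        self.summary_ = {
            "n_dmrs": int(len(dmrs)),
            "total_bp": int((dmrs["end"] - dmrs["start"]).sum()) if len(dmrs) else 0,
            "mean_abs_diff": float(dmrs["diff"].abs().mean()) if len(dmrs) else float("nan"),
        }
        return self

    def predict(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "dmrs_"):
            raise NotFittedError("DmrCaller must be fitted first")
        return self.dmrs_


# ---------------------------------------------------------------------------
# set comparison


def _merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    merged: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        iv = sub[["start", "end"]].sort_values("start").to_numpy()
        out = []
        for s, e in iv:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64).reshape(-1, 2)
    return merged


def _overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: >=1 bp overlap with any subject interval."""
    hits = np.zeros(len(query), dtype=bool)
    subj = {c: s for c, s in subject.groupby("chrom", sort=False)}
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in subj:
            continue
        s_sorted = np.sort(subj[chrom]["start"].to_numpy())
        e_sorted = np.sort(subj[chrom]["end"].to_numpy())
        n = len(s_sorted)
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        before = np.searchsorted(e_sorted, qs, side="right")  # end <= qs
        after = n - np.searchsorted(s_sorted, qe, side="left")  # start >= qe
        hits[sub.index.to_numpy()] = (n - before - after) > 0
    return hits


def _intersection_bp(m1: dict[str, np.ndarray], m2: dict[str, np.ndarray]) -> int:
    total = 0
    for chrom, a in m1.items():
        b = m2.get(chrom)
        if b is None or not len(a) or not len(b):
            continue
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def compare_dmr_sets(dmrs_1: pd.DataFrame, dmrs_2: pd.DataFrame) -> dict:
    """Overlap summary of two DMR sets: shared/specific counts and bp Jaccard."""
    d1 = dmrs_1.reset_index(drop=True)
    d2 = dmrs_2.reset_index(drop=True)
    shared_1 = _overlap_any(d1, d2)
    shared_2 = _overlap_any(d2, d1)
    m1, m2 = _merge_intervals(d1), _merge_intervals(d2)
    bp1 = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in m1.values())
    bp2 = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in m2.values())
    inter = _intersection_bp(m1, m2)
    union = bp1 + bp2 - inter
    return {
        "n_1": len(d1),
        "n_2": len(d2),
        "shared_1": int(shared_1.sum()),
        "shared_2": int(shared_2.sum()),
        "specific_1": int((~shared_1).sum()),
        "specific_2": int((~shared_2).sum()),
        "bp_1": bp1,
        "bp_2": bp2,
        "bp_intersection": inter,
        "bp_jaccard": (inter / union) if union else float("nan"),
    }
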