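"""Global, binned and feature-centered methylation levels per context.

Levels are *weighted*: the sum of methylated calls divided by the sum of
total calls over the qualifying sites (coverage-weighted), optionally
NCR-corrected.  A per-site-mean alternative is exposed behind a flag.  The
CH context is the union of CA, CC and CT; its level is by construction the
coverage-weighted combination of the three subcontexts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import correct_mc_fraction
from .simulate import context_class

__all__ = [
    "ContextLevel",
    "global_level",
    "binned_levels",
    "stratified_difference",
    "profile_at_features",
]

CH_SUBCONTEXTS = ("CA", "CC", "CT")
_VALID_CONTEXTS = ("CG", "CH") + CH_SUBCONTEXTS


@dataclass
class ContextLevel:
    sample: str | None
    context: str
    level: float
    n_sites: int
    mc_sum: int
    cov_sum: int


def _context_mask(table: pd.DataFrame, context: str) -> pd.Series:
    if context not in _VALID_CONTEXTS:
        raise ValueError(f"context must be one of {_VALID_CONTEXTS}, got {context!r}")
    cls = (
        table["context_class"]
        if "context_class" in table.columns
        else context_class(table["context"])
    )
    if context == "CH":
        return cls.isin(CH_SUBCONTEXTS)
    return cls == context


def global_level(
    table: pd.DataFrame,
    context: str = "CG",
    min_coverage: int = 1,
    ncr: float = 0.0,
    per_site_mean: bool = False,
    sample: str | None = None,
) -> ContextLevel:
    """Genome-wide weighted methylation level for one context.

    With no qualifying sites the level is NaN (explicit empty result).
    ``per_site_mean=True`` averages per-site fractions instead of pooling
    counts.
    """
    sub = table[_context_mask(table, context) & (table["total_count"] >= min_coverage)]
    mc, cov = int(sub["mc_count"].sum()), int(sub["total_count"].sum())
    if cov == 0:
        level = float("nan")
    elif per_site_mean:
        level = float(
            np.mean(correct_mc_fraction(sub["mc_count"] / sub["total_count"], ncr))
        )
    else:
        level = float(correct_mc_fraction(mc / cov, ncr))
    return ContextLevel(sample, context, level, len(sub), mc, cov)


def binned_levels(
    table: pd.DataFrame,
    bin_size: int = 1000,
    context: str = "CG",
    ncr: float = 0.0,
    by: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pooled levels over fixed, 0-based half-open genomic bins.

    Numerators and denominators per bin sum exactly to the global values
    (conservation).  ``by`` adds grouping columns (e.g. ``("sample",)``).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    sub = table[_context_mask(table, context)].copy()
    sub["bin_start"] = ((sub["pos"] - 1) // bin_size) * bin_size
    keys = list(by) + ["chrom", "bin_start"]
    out = (
        sub.groupby(keys, observed=True)[["mc_count", "total_count"]]
        .sum()
        .reset_index()
    )
    out["level"] = correct_mc_fraction(
        out["mc_count"] / out["total_count"].where(out["total_count"] > 0, 1), ncr
    )
    out.loc[out["total_count"] == 0, "level"] = np.nan
    return out


def stratified_difference(
    stratifier: pd.Series,
    effect: pd.Series,
    edges,
) -> pd.DataFrame:
    """Median of ``effect`` within strata of ``stratifier`` (index-aligned).

    Used to summarize, e.g., the median treatment difference in bin-level
    methylation stratified by the regional (dorsal - ventral) difference.
    """
    edges = np.asarray(edges, dtype=float)
    joined = pd.DataFrame({"x": stratifier, "y": effect}).dropna()
    strata = pd.cut(joined["x"], edges)
    grouped = joined.groupby(strata, observed=False)["y"]
    out = pd.DataFrame(
        {
            "stratum_left": edges[:-1],
            "stratum_right": edges[1:],
            "median_effect": grouped.median().to_numpy(),
            "n_bins": grouped.size().to_numpy(),
        }
    )
    return out


def profile_at_features(
    table: pd.DataFrame,
    features: pd.DataFrame,
    flank_bp: int = 2000,
    step_bp: int = 100,
    context: str = "CG",
    min_site_cov: int = 3,
    min_sites: int = 1,
    ncr: float = 0.0,
) -> pd.DataFrame:
    """Pooled methylation profile centered on feature midpoints.

    Sites within ``flank_bp`` of each feature midpoint are assigned to
    strand-oriented offset bins (minus-strand features have offsets negated,
    so profiles read 5'->3').  The mean per bin is the coverage-weighted
    level; bins with fewer than ``min_sites`` contributing sites report NaN.
    Offsets use half-open bins over ``[-flank_bp, flank_bp)``.
    """
    if step_bp <= 0 or flank_bp <= 0 or flank_bp % step_bp:
        raise ValueError("flank_bp must be a positive multiple of step_bp")
    edges = np.arange(-flank_bp, flank_bp + step_bp, step_bp)
    nbins = len(edges) - 1
    mc_sum = np.zeros(nbins)
    cov_sum = np.zeros(nbins)
    n_sites = np.zeros(nbins, dtype=int)

    sub = table[_context_mask(table, context) & (table["total_count"] >= min_site_cov)]
    if not features.empty and not sub.empty:
        for chrom, feats in features.groupby("chrom", sort=False):
            sites = sub[sub["chrom"] == chrom].sort_values("pos")
            if sites.empty:
                continue
            pos0 = sites["pos"].to_numpy() - 1
            mc = sites["mc_count"].to_numpy()
            cov = sites["total_count"].to_numpy()
            for _, f in feats.iterrows():
                center = (int(f["start"]) + int(f["end"])) // 2
                lo = np.searchsorted(pos0, center - flank_bp, side="left")
                hi = np.searchsorted(pos0, center + flank_bp, side="left")
                if hi <= lo:
                    continue
                rel = pos0[lo:hi] - center
                if f.get("strand", "+") == "-":
                    rel = -rel
                keep = (rel >= -flank_bp) & (rel < flank_bp)
                b = (rel[keep] + flank_bp) // step_bp
                np.add.at(mc_sum, b, mc[lo:hi][keep])
                np.add.at(cov_sum, b, cov[lo:hi][keep])
                np.add.at(n_sites, b, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        level = correct_mc_fraction(
            np.where(cov_sum > 0, mc_sum / np.where(cov_sum > 0, cov_sum, 1), np.nan),
            ncr,
        )
    level = np.where(n_sites >= min_sites, level, np.nan)
    return pd.DataFrame(
        {
            "offset": edges[:-1] + step_bp / 2.0,
            "level": level,
            "n_sites": n_sites,
            "mc_sum": mc_sum,
            "cov_sum": cov_sum,
        }
    )
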