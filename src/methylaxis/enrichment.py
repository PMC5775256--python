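"""DMR-gene and peak-DMR association statistics.

The central quantity is a TSS-distance enrichment curve: the density of
DMRs per gene per megabase as a function of strand-oriented distance from
the transcription start site (upstream negative).  Every gene within the
window is paired with every DMR (per-gene density normalization), so
duplicating the gene set leaves the score unchanged.  Significance against
expression comes from two devices:

* a resampled control band — control gene sets drawn to match the target
  set's composition across strata (deciles) of mean expression, giving a
  per-bin 2.5/97.5 percentile envelope; and
* hypergeometric urn tests, both for DMR-containing genes (target vs all
  genes) and for peak/DMR colocalization (peaks whose midpoint lies within
  ``max_dist`` of a DMR, against a universe of fixed-width genome windows).

Intervals are BED-convention 0-based half-open; distance comparisons are
closed (a midpoint exactly ``max_dist`` away counts as a hit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "tss_distance",
    "pair_distances",
    "enrichment_curve",
    "matched_control_band",
    "dmr_gene_hypergeom",
    "gene_dmr_fraction",
    "peak_dmr_colocalization",
    "ColocalizationResult",
    "TssEnrichment",
]

DEFAULT_WINDOW = 1_000_000
DEFAULT_BIN = 100_000


def _default_edges(window: int = DEFAULT_WINDOW, bin_bp: int = DEFAULT_BIN) -> np.ndarray:
    return np.arange(-window, window + bin_bp, bin_bp, dtype=float)


def _midpoints(intervals: pd.DataFrame) -> np.ndarray:
    return (intervals["start"].to_numpy() + intervals["end"].to_numpy()) / 2.0


def tss_distance(dmr, gene) -> float:
    """Signed bp from a gene's TSS to a DMR midpoint, strand-oriented.

    Positive downstream of the TSS, negative upstream; for a minus-strand
    gene upstream lies at larger coordinates.  ``dmr`` and ``gene`` are
    mapping-like rows with BED fields (gene also ``tss`` and ``strand``).
    Different chromosomes have no distance (returns None).
    """
    if dmr["chrom"] != gene["chrom"]:
        return None
    mid = (dmr["start"] + dmr["end"]) / 2.0
    d = mid - gene["tss"]
    return float(-d if gene["strand"] == "-" else d)


def pair_distances(
    dmrs: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """All (gene, DMR) pairs within ``window`` bp of the TSS, with signed distance."""
    rows_gene, rows_dmr, dists = [], [], []
    dmr_by_chrom = {c: s.reset_index() for c, s in dmrs.groupby("chrom", sort=False)}
    for gi, g in genes.reset_index(drop=True).iterrows():
        sub = dmr_by_chrom.get(g["chrom"])
        if sub is None:
            continue
        mids = _midpoints(sub)
        order = np.argsort(mids)
        mids_sorted = mids[order]
        lo = np.searchsorted(mids_sorted, g["tss"] - window, side="left")
        hi = np.searchsorted(mids_sorted, g["tss"] + window, side="right")
        for k in range(lo, hi):
            d = mids_sorted[k] - g["tss"]
            if g["strand"] == "-":
                d = -d
            rows_gene.append(gi)
            rows_dmr.append(int(sub["index"].iloc[order[k]]))
            dists.append(d)
    return pd.DataFrame({"gene_idx": rows_gene, "dmr_idx": rows_dmr, "distance": dists})


def _per_gene_bincounts(
    dmrs: pd.DataFrame, genes: pd.DataFrame, edges: np.ndarray, window: int
) -> np.ndarray:
    """Matrix (n_genes x n_bins) of DMR counts per distance bin."""
    pairs = pair_distances(dmrs, genes, window)
    n_bins = len(edges) - 1
    mat = np.zeros((len(genes), n_bins))
    if len(pairs):
        b = np.digitize(pairs["distance"].to_numpy(), edges) - 1
        ok = (b >= 0) & (b < n_bins)
        np.add.at(mat, (pairs["gene_idx"].to_numpy()[ok], b[ok]), 1.0)
    return mat


def _score_from_counts(counts: np.ndarray, edges: np.ndarray, n_genes: int) -> np.ndarray:
    widths_mb = np.diff(edges) / 1e6
    if (widths_mb <= 0).any():
        raise ValueError("bin edges must be strictly increasing (zero-width bin)")
    return counts / (n_genes * widths_mb)


def enrichment_curve(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    bins=None,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """DMR density per gene per Mb in strand-oriented TSS-distance bins."""
    if genes.empty:
        raise ValueError("enrichment_curve needs a nonempty gene set")
    edges = _default_edges(window) if bins is None else np.asarray(bins, dtype=float)
    mat = _per_gene_bincounts(dmrs, genes, edges, window)
    score = _score_from_counts(mat.sum(axis=0), edges, len(genes))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "score": score}
    )


def _stratum_labels(expression: pd.Series, n_strata: int) -> pd.Series:
    return pd.qcut(expression.rank(method="first"), n_strata, labels=False)


def matched_control_band(
    dmrs: pd.DataFrame,
    target_genes,
    genes: pd.DataFrame,
    expression: pd.Series,
    bins=None,
    window: int = DEFAULT_WINDOW,
    n_resamples: int = 1000,
    seed=None,
    n_strata: int = 10,
) -> pd.DataFrame:
    """95% control envelope from expression-matched resampled gene sets.

    Genes are stratified into ``n_strata`` quantile bins of mean expression;
    each resample draws, without replacement and excluding target genes, a
    control set matching the target's per-stratum composition.  When a
    stratum lacks enough non-target genes the deficit is drawn from the
    nearest neighbouring strata (with a warning).  Returns per-bin 2.5/97.5
    percentiles of the control curves plus the target curve.
    """
    if not len(target_genes):
        raise ValueError("empty target gene set")
    genes = genes.reset_index(drop=True)
    target_mask = genes["name"].isin(set(target_genes)).to_numpy()
    if target_mask.sum() >= len(genes):
        raise ValueError("need more genes than target genes to draw controls")
    edges = _default_edges(window) if bins is None else np.asarray(bins, dtype=float)
    mat = _per_gene_bincounts(dmrs, genes, edges, window)
    n_target = int(target_mask.sum())
    target_curve = _score_from_counts(mat[target_mask].sum(axis=0), edges, n_target)

    expr = expression.reindex(genes["name"]).to_numpy()
    if np.isnan(expr).any():
        raise ValueError("expression missing for some genes")
    strata = _stratum_labels(pd.Series(expr), n_strata).to_numpy()
    rng = np.random.default_rng(seed)
    pools = {
        s: np.flatnonzero((strata == s) & ~target_mask) for s in np.unique(strata)
    }
    need = {
        s: int(((strata == s) & target_mask).sum()) for s in np.unique(strata)
    }
    # relax strata whose control pool is too small
    order = sorted(need)
    for s in order:
        while need[s] > len(pools[s]):
            neighbours = sorted(
                (abs(o - s), o) for o in order if o != s and len(pools[o]) > need[o]
            )
            if not neighbours:
                raise ValueError("not enough control genes in any stratum")
            _, o = neighbours[0]
            warnings.warn(
                f"expression stratum {s} has too few control genes; borrowing from stratum {o}"
            )
            need[s] -= 1
            need[o] += 1

    curves = np.empty((n_resamples, len(edges) - 1))
    for i in range(n_resamples):
        picked = np.concatenate(
            [
                rng.choice(pools[s], size=need[s], replace=False)
                for s in order
                if need[s] > 0
            ]
        )
        curves[i] = _score_from_counts(mat[picked].sum(axis=0), edges, len(picked))
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "score": target_curve,
            "band_low": lo,
            "band_high": hi,
        }
    )


def dmr_gene_hypergeom(target_genes, all_genes, gene_has_dmr) -> float:
    """Upper-tail hypergeometric p for DMR-containing genes in the target set.

    Urn: population = all genes, successes = genes flagged as containing a
    DMR, sample = the target genes, observed = flagged target genes.
    """
    all_genes = list(all_genes)
    target = set(target_genes)
    if not target:
        raise ValueError("empty target gene set")
    flags = pd.Series(gene_has_dmr)
    if not set(all_genes) <= set(flags.index):
        flags = pd.Series(np.asarray(gene_has_dmr, dtype=bool), index=all_genes)
    missing = [g for g in all_genes if g not in flags.index]
    if missing:
        raise ValueError(f"gene_has_dmr undefined for {len(missing)} genes")
    M = len(all_genes)
    K = int(flags.loc[all_genes].sum())
    n = len(target)
    k = int(flags.loc[list(target)].sum())
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def gene_dmr_fraction(genes: pd.DataFrame, dmrs: pd.DataFrame, span: int = 10_000):
    """Fraction of genes with >=1 DMR within gene body +/- ``span`` bp.

    Returns ``(fraction, flags)`` with flags indexed by gene name.
    """
    flags = np.zeros(len(genes), dtype=bool)
    genes = genes.reset_index(drop=True)
    dmr_by_chrom = {c: s for c, s in dmrs.groupby("chrom", sort=False)}
    for chrom, sub in genes.groupby("chrom", sort=False):
        d = dmr_by_chrom.get(chrom)
        if d is None:
            continue
        s_sorted = np.sort(d["start"].to_numpy())
        e_sorted = np.sort(d["end"].to_numpy())
        n = len(s_sorted)
        qs = np.maximum(sub["start"].to_numpy() - span, 0)
        qe = sub["end"].to_numpy() + span
        before = np.searchsorted(e_sorted, qs, side="right")
        after = n - np.searchsorted(s_sorted, qe, side="left")
        flags[sub.index.to_numpy()] = (n - before - after) > 0
    frac = float(flags.mean()) if len(genes) else 0.0
    return frac, pd.Series(flags, index=genes["name"], name="has_dmr")


@dataclass
class ColocalizationResult:
    n_peaks: int
    n_peaks_near_dmr: int
    max_dist: int
    universe_size: int
    n_successes: int
    p_value: float
    pairs: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_peaks_near_dmr": self.n_peaks_near_dmr,
            "max_dist": self.max_dist,
            "universe_size": self.universe_size,
            "n_successes": self.n_successes,
            "p_value": self.p_value,
        }


def _near_dmr(intervals: pd.DataFrame, dmrs: pd.DataFrame, max_dist: int) -> np.ndarray:
    """Midpoint of each interval within ``max_dist`` (closed) of a DMR."""
    hits = np.zeros(len(intervals), dtype=bool)
    intervals = intervals.reset_index(drop=True)
    by_chrom = {c: s for c, s in dmrs.groupby("chrom", sort=False)}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        d = by_chrom.get(chrom)
        if d is None:
            continue
        # distance 0 inside [start, end]; grow by max_dist and test containment
        s_sorted = np.sort(d["start"].to_numpy() - max_dist)
        e_sorted = np.sort(d["end"].to_numpy() + max_dist)
        n = len(s_sorted)
        mids = _midpoints(sub)
        before = np.searchsorted(e_sorted, mids, side="left")  # end+max < mid
        after = n - np.searchsorted(s_sorted, mids, side="right")  # start-max > mid
        hits[sub.index.to_numpy()] = (n - before - after) > 0
    return hits


def _tile_genome(chrom_sizes, window_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, window_bp)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + window_bp, size))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def peak_dmr_colocalization(
    peaks: pd.DataFrame,
    dmrs: pd.DataFrame,
    max_dist: int = 500,
    universe: pd.DataFrame | None = None,
    chrom_sizes=None,
    window_bp: int = 500,
) -> ColocalizationResult:
    """Hypergeometric test of peaks falling near DMRs.

    A peak *hits* when its midpoint lies within ``max_dist`` bp (closed) of a
    DMR edge.  The urn population is ``universe`` (default: fixed-width
    ``window_bp`` windows tiling ``chrom_sizes``), successes are universe
    intervals near a DMR by the same rule, and the sample is the peak set.
    """
    if peaks.empty:
        raise ValueError("empty peak set")
    if universe is None:
        if chrom_sizes is None:
            raise ValueError("need either a universe or chrom_sizes to tile")
        universe = _tile_genome(chrom_sizes, window_bp)
    peak_hits = _near_dmr(peaks, dmrs, max_dist)
    succ = int(_near_dmr(universe, dmrs, max_dist).sum())
    k = int(peak_hits.sum())
    p = float(stats.hypergeom.sf(k - 1, len(universe), succ, len(peaks)))

    rows = []
    dmr_reset = dmrs.reset_index(drop=True)
    for pi in np.flatnonzero(peak_hits):
        peak = peaks.iloc[pi]
        mid = (peak["start"] + peak["end"]) / 2.0
        same = dmr_reset[dmr_reset["chrom"] == peak["chrom"]]
        dist = np.maximum.reduce(
            [
                same["start"].to_numpy() - mid,
                mid - same["end"].to_numpy(),
                np.zeros(len(same)),
            ]
        )
        j = int(np.argmin(dist))
        rows.append((pi, int(same.index[j]), float(dist[j])))
    pairs = pd.DataFrame(rows, columns=["peak_idx", "dmr_idx", "distance"])
    return ColocalizationResult(
        n_peaks=len(peaks),
        n_peaks_near_dmr=k,
        max_dist=max_dist,
        universe_size=len(universe),
        n_successes=succ,
        p_value=p,
        pairs=pairs,
    )


class TssEnrichment(BaseEstimator):
    """Estimator-style TSS-distance enrichment with a matched control band.

    ``fit(dmrs, genes, target_genes=None, expression=None)`` computes
    ``curve_`` for the target set (all genes when no target given) and, when
    both a target set and per-gene mean expression are supplied, the
    expression-matched ``band_``.
    """

    def __init__(
        self,
        bins=None,
        window: int = DEFAULT_WINDOW,
        n_resamples: int = 1000,
        seed=None,
        n_strata: int = 10,
    ):
        self.bins = bins
        self.window = window
        self.n_resamples = n_resamples
        self.seed = seed
        self.n_strata = n_strata

    def fit(self, dmrs, genes, target_genes=None, expression=None):
        if target_genes is None:
            self.curve_ = enrichment_curve(dmrs, genes, self.bins, self.window)
            self.band_ = None
            return self
        sub = genes[genes["name"].isin(set(target_genes))]
        self.curve_ = enrichment_curve(dmrs, sub, self.bins, self.window)
        if expression is not None:
            self.band_ = matched_control_band(
                dmrs,
                target_genes,
                genes,
                expression,
                bins=self.bins,
                window=self.window,
                n_resamples=self.n_resamples,
                seed=self.seed,
                n_strata=self.n_strata,
            )
        else:
            self.band_ = None
        return self
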