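"""Gene filtering, QC and contrast-based differential expression.

The test is a fully specified substitute for a negative-binomial GLM:
counts are normalized by median-of-ratios size factors, log2-transformed
with a pseudocount, and each contrast is tested with a Welch-style t
statistic on the linear combination of group means (Satterthwaite degrees
of freedom).  Benjamini-Hochberg controls the FDR across retained genes
within each contrast; a gene is called differentially expressed when
q < 0.05 and its linear fold change is at least 20% (|log2FC| >= log2 1.2).

Three contrasts over the 2x2 region (dorsal/ventral) x condition (SH/EE)
design are supported:

* ``region``:     (dorsal SH - ventral SH) - (dorsal EE - ventral EE) = 0
* ``ee-dorsal``:  dorsal EE - dorsal SH = 0
* ``ee-ventral``: ventral EE - ventral SH = 0
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_genes",
    "tpm",
    "size_factors",
    "norm_cpm",
    "xist_qc",
    "de_test",
    "sample_structure",
    "DifferentialExpression",
    "CONTRASTS",
]

#: contrast name -> {cell: coefficient}; cells are "<region>_<condition>"
CONTRASTS = {
    "region": {"dorsal_SH": 1.0, "ventral_SH": -1.0, "dorsal_EE": -1.0, "ventral_EE": 1.0},
    "ee-dorsal": {"dorsal_EE": 1.0, "dorsal_SH": -1.0},
    "ee-ventral": {"ventral_EE": 1.0, "ventral_SH": -1.0},
}


def filter_genes(
    counts: pd.DataFrame,
    mode: str = "counts",
    min_count: int = 10,
    min_samples: int = 2,
    min_tpm: float = 1.0,
    min_tpm_samples: int = 3,
    gene_lengths: pd.Series | None = None,
) -> pd.Index:
    """Genes retained for analysis.

    ``mode="counts"`` keeps genes with counts strictly greater than
    ``min_count`` in at least ``min_samples`` samples (the default rule);
    ``mode="tpm"`` keeps genes with TPM > ``min_tpm`` in at least
    ``min_tpm_samples`` samples and needs ``gene_lengths`` (bp).
    """
    if mode == "counts":
        keep = (counts > min_count).sum(axis=1) >= min_samples
    elif mode == "tpm":
        if gene_lengths is None:
            raise ValueError("tpm filtering requires gene_lengths")
        t = tpm(counts, gene_lengths)
        keep = (t > min_tpm).sum(axis=1) >= min_tpm_samples
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    retained = counts.index[keep]
    retained = pd.Index(retained)
    return retained


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million with effective length = exonic length (bp)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing for some genes")
    rate = counts.div(lengths / 1e3, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = log_counts.notna().all(axis=1) & np.isfinite(log_geo)
    if usable.sum() == 0:
        # degenerate fall-back: library-size ratios
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.log(totals).mean())
        return sf
    ratios = log_counts.loc[usable].sub(log_geo.loc[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def norm_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts normalized by median-of-ratios factors, scaled so the average
    normalized library totals one million."""
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    scale = 1e6 / norm.sum(axis=0).mean()
    return norm * scale


def _plain_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    return counts.div(totals.where(totals > 0, 1), axis=1) * 1e6


def xist_qc(
    counts: pd.DataFrame,
    marker_gene: str = "Xist",
    k: float = 5.0,
    mad_floor: float | None = None,
) -> list[str]:
    """Samples whose marker CPM exceeds median + k * MAD — flagged, never
    silently dropped.  A missing marker warns and flags nothing.

    ``mad_floor`` (CPM) guards the degenerate case of a marker at or near
    zero everywhere, where the MAD collapses to 0 and shot noise would flag
    arbitrary samples.  The default floor is the CPM equivalent of five
    reads in the median library (at least 1 CPM); a genuinely contaminated
    sample sits orders of magnitude above it.
    """
    if marker_gene not in counts.index:
        warnings.warn(f"marker gene {marker_gene!r} absent; no samples flagged")
        return []
    if mad_floor is None:
        med_lib = float(counts.sum(axis=0).median())
        mad_floor = max(1.0, 5e6 / med_lib) if med_lib > 0 else 1.0
    x = _plain_cpm(counts).loc[marker_gene]
    med = float(x.median())
    mad = float((x - med).abs().median())
    flagged = x.index[x > med + k * max(mad, mad_floor)].tolist()
    return flagged


def _cells(samples: pd.DataFrame) -> pd.Series:
    return samples["region"].astype(str) + "_" + samples["condition"].astype(str)


def de_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: str = "region",
    fc_threshold: float = 1.2,
    q_threshold: float = 0.05,
    pseudocount: float = 0.5,
    retained: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene contrast estimate, Welch p, BH q and DE call.

    BH runs across retained genes only; non-retained genes keep their
    statistics but get ``q = NaN`` and ``de_call = False``
    (``passes_filters`` records the distinction).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    coeffs = CONTRASTS[contrast]
    cells = _cells(samples)
    cols_by_cell = {}
    for cell in coeffs:
        cols = samples.index[cells == cell]
        if len(cols) < 2:
            raise ValueError(
                f"contrast {contrast!r} needs >=2 samples in cell {cell!r}, found {len(cols)}"
            )
        cols_by_cell[cell] = cols

    log_expr = np.log2(norm_cpm(counts) + pseudocount)
    est = np.zeros(len(counts))
    var = np.zeros(len(counts))
    df_num = np.zeros(len(counts))
    df_den = np.zeros(len(counts))
    for cell, c in coeffs.items():
        sub = log_expr[cols_by_cell[cell]]
        n = sub.shape[1]
        m = sub.mean(axis=1).to_numpy()
        s2 = sub.var(axis=1, ddof=1).to_numpy()
        est += c * m
        term = (c**2) * s2 / n
        var += term
        df_den += term**2 / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dof = np.where(df_den > 0, var**2 / np.where(df_den > 0, df_den, 1.0), 1.0)
        tstat = np.where(var > 0, est / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(var > 0, p, 1.0)

    out = pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": est,
            "p": p,
            "q": np.nan,
            "contrast": contrast,
            "passes_filters": True,
        }
    ).set_index("gene", drop=False)
    if retained is not None:
        out["passes_filters"] = out.index.isin(retained)
    mask = out["passes_filters"].to_numpy()
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["de_call"] = (
        (out["q"] < q_threshold)
        & (out["log2fc"].abs() >= np.log2(fc_threshold))
        & out["passes_filters"]
    )
    return out


def sample_structure(counts: pd.DataFrame, n_components: int = 3) -> pd.DataFrame:
    """PCA projection of samples on centered log2 CPM (QC view of the design).

    Returns a samples x components frame; ``attrs['explained_variance_ratio']``
    carries the variance explained per component.
    """
    if counts.shape[1] < 3:
        raise ValueError("sample_structure needs at least 3 samples")
    x = np.log2(_plain_cpm(counts) + 0.5)
    x = x.sub(x.mean(axis=1), axis=0)  # center genes
    n_components = min(n_components, counts.shape[1] - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(x.to_numpy().T)
    out = pd.DataFrame(
        proj,
        index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(proj.shape[1])],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out


class DifferentialExpression(BaseEstimator):
    """End-to-end DE pipeline as a fit-style estimator.

    ``fit(counts, samples)`` runs marker-gene QC (optional), the gene
    filter, and the contrast test; fitted attributes are
    ``excluded_samples_``, ``retained_``, ``results_`` and ``de_genes_``.
    """

    def __init__(
        self,
        contrast: str = "region",
        fc_threshold: float = 1.2,
        q_threshold: float = 0.05,
        pseudocount: float = 0.5,
        filter_mode: str = "counts",
        min_count: int = 10,
        min_samples: int = 2,
        xist_marker: str | None = None,
        xist_k: float = 5.0,
    ):
        self.contrast = contrast
        self.fc_threshold = fc_threshold
        self.q_threshold = q_threshold
        self.pseudocount = pseudocount
        self.filter_mode = filter_mode
        self.min_count = min_count
        self.min_samples = min_samples
        self.xist_marker = xist_marker
        self.xist_k = xist_k

    def fit(self, counts: pd.DataFrame, samples: pd.DataFrame):
        excluded: list[str] = []
        if self.xist_marker is not None:
            excluded = xist_qc(counts, self.xist_marker, self.xist_k)
        self.excluded_samples_ = excluded
        kept_cols = [c for c in counts.columns if c not in excluded]
        counts = counts[kept_cols]
        samples = samples.loc[kept_cols]
        self.retained_ = filter_genes(
            counts,
            mode=self.filter_mode,
            min_count=self.min_count,
            min_samples=self.min_samples,
        )
        self.results_ = de_test(
            counts,
            samples,
            contrast=self.contrast,
            fc_threshold=self.fc_threshold,
            q_threshold=self.q_threshold,
            pseudocount=self.pseudocount,
            retained=self.retained_,
        )
        self.de_genes_ = self.results_.index[self.results_["de_call"]].tolist()
        return self
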