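"""Spike-in error-rate estimation and maximum-likelihood signal correction.

Bisulfite sequencing reads both mC and hmC as methylated, and unmethylated
cytosines fail conversion at the non-conversion rate (NCR).  The corrected
total methylation fraction is the maximum-likelihood inversion

    p_mC = g[ (m/c - NCR) / (1 - NCR) ],        g[x] = max(x, 0),

with ``m`` methylated calls out of ``c`` total calls.  TAB-Seq protects hmC
(glucosylation) and oxidizes mC, so only hmC should survive conversion; with
``r`` the TAB bisulfite non-conversion rate, ``s`` the non-oxidation rate,
``t`` the non-protection rate and ``p_mC`` the (BS-corrected) fraction of
mC + hmC, the corrected hydroxymethylation level is

    p_hmC = g[ (q_TAB - s * p_mC - r * (1 - p_mC)) / (1 - t) ].

Rates are pooled across each control contig (ratio of sums — the binomial
MLE, weighting sites by coverage).  ``r`` comes from the unmethylated
contig, ``s`` from CG sites of the fully methylated contig, and ``t`` from
the hydroxymethylated contig after correcting for its true hmC abundance
``a`` (measured from a matched BS run of the same material, since the
commercial spike-in is not 100% hydroxymethylated):

    q_C = (1 - t) * a + s * a + r * (1 - a)   =>   t solved linearly.

Both corrections additionally clamp above (p_mC <= 1, p_hmC <= p_mC):
sampling noise can push estimates over the ceiling, and levels must stay in
the probability simplex.  Clamp events are counted on corrected tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError
from statsmodels.stats.proportion import proportion_confint

from .simulate import SPIKE_HMC, SPIKE_METH, SPIKE_UNMETH, context_class

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "ZeroCoverageError",
    "RateEstimate",
    "CalibrationRates",
    "estimate_ncr",
    "estimate_tab_rates",
    "estimate_all_rates",
    "correct_mc",
    "correct_mc_fraction",
    "correct_hmc",
    "correct_table",
    "SpikeInCalibrator",
]


class CalibrationError(ValueError):
    """Invalid calibration inputs or unidentifiable rates."""


class ZeroCoverageError(CalibrationError):
    """A correction was requested at a site with no coverage."""


@dataclass
class RateEstimate:
    """A pooled binomial rate with its 95% confidence interval."""

    rate: float
    numerator: float
    denominator: float
    ci_low: float
    ci_high: float
    method: str = "clopper-pearson"

    def __post_init__(self):
        if self.denominator <= 0:
            raise CalibrationError("rate estimate needs a positive denominator")
        if not (self.ci_low - 1e-12 <= self.rate <= self.ci_high + 1e-12):
            raise CalibrationError("confidence interval does not bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "rate": float(self.rate),
            "numerator": float(self.numerator),
            "denominator": float(self.denominator),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateEstimate":
        return cls(**d)


@dataclass
class CalibrationRates:
    """The four assay error rates: NCR (BS) and r, s, t (TAB)."""

    ncr: RateEstimate | None = None
    r_tab: RateEstimate | None = None
    s_tab: RateEstimate | None = None
    t_tab: RateEstimate | None = None

    def to_dict(self) -> dict:
        return {
            k: (v.to_dict() if v is not None else None)
            for k, v in (
                ("ncr", self.ncr),
                ("r_tab", self.r_tab),
                ("s_tab", self.s_tab),
                ("t_tab", self.t_tab),
            )
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationRates":
        return cls(
            **{
                k: (RateEstimate.from_dict(v) if v else None)
                for k, v in d.items()
            }
        )


def _pooled_rate(mc: float, total: float, method="clopper-pearson") -> RateEstimate:
    if total <= 0:
        raise ZeroCoverageError("no coverage to estimate a rate from")
    lo, hi = proportion_confint(mc, total, alpha=0.05, method="beta")
    return RateEstimate(mc / total, mc, total, float(lo), float(hi), method)


def _restrict_contig(table: pd.DataFrame, contig: str | None, what: str) -> pd.DataFrame:
    if contig is None:
        return table
    known = table["chrom"] == contig
    if (~known).any() and table.loc[~known, "mc_count"].sum() > 0:
        warnings.warn(
            f"{what}: table carries counts on contigs other than {contig!r}; ignoring them",
            stacklevel=3,
        )
    return table[known]


def estimate_ncr(spikein_bs: pd.DataFrame, contig: str | None = None) -> RateEstimate:
    """Bisulfite non-conversion rate from the fully unmethylated spike-in.

    Pools all cytosines of the contig: ``rate = sum(m) / sum(c)`` with a
    Clopper-Pearson 95% CI.
    """
    t = _restrict_contig(spikein_bs, contig, "estimate_ncr")
    return _pooled_rate(float(t["mc_count"].sum()), float(t["total_count"].sum()))


def correct_mc_fraction(frac, ncr: float):
    """NCR-corrected methylation fraction, clamped to [0, 1]."""
    if ncr >= 1.0:
        raise CalibrationError(f"ncr={ncr} must be < 1")
    return np.clip((np.asarray(frac, dtype=float) - ncr) / (1.0 - ncr), 0.0, 1.0)


def correct_mc(m, c, ncr: float):
    """NCR-corrected methylation level from counts ``m`` of ``c``.

    ``c == 0`` is signalled distinctly (ZeroCoverageError) rather than
    silently returning 0.
    """
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    if (c <= 0).any():
        raise ZeroCoverageError("correct_mc requires coverage > 0 at every site")
    if ((m < 0) | (m > c)).any():
        raise CalibrationError("need 0 <= m <= c")
    out = correct_mc_fraction(m / c, ncr)
    return float(out) if out.ndim == 0 else out


def _rate_value(r) -> float:
    return r.rate if isinstance(r, RateEstimate) else float(r)


def _get_rst(rates) -> tuple[float, float, float]:
    if isinstance(rates, CalibrationRates):
        return (
            _rate_value(rates.r_tab),
            _rate_value(rates.s_tab),
            _rate_value(rates.t_tab),
        )
    r, s, t = rates
    return float(r), float(s), float(t)


def correct_hmc(q_tab, p_mc, rates):
    """Corrected hydroxymethylation level, clamped to [0, min(1, p_mc)].

    ``p_mc`` is the NCR-corrected mC+hmC fraction from the matched BS sample
    at the same site; ``rates`` is a :class:`CalibrationRates` or an
    ``(r, s, t)`` triple.
    """
    r, s, t = _get_rst(rates)
    if t >= 1.0:
        raise CalibrationError(f"t_tab={t} must be < 1")
    q = np.asarray(q_tab, dtype=float)
    p = np.asarray(p_mc, dtype=float)
    raw = (q - s * p - r * (1.0 - p)) / (1.0 - t)
    out = np.clip(raw, 0.0, np.minimum(1.0, p))
    return float(out) if out.ndim == 0 else out


def estimate_tab_rates(
    spikein_tab: pd.DataFrame,
    spikein_c_bs: pd.DataFrame,
    ncr: float = 0.0,
    unmeth_contig: str = SPIKE_UNMETH,
    meth_contig: str = SPIKE_METH,
    hmc_contig: str = SPIKE_HMC,
) -> CalibrationRates:
    """Estimate (r, s, t) from the TAB spike-in contigs.

    * ``r``: unconverted fraction over all cytosines of the unmethylated
      contig;
    * ``s``: unconverted fraction at CG sites of the fully methylated contig;
    * ``t``: from the hmC contig's unconverted CG fraction ``q_C`` after
      correcting for its true hmC abundance ``a`` (NCR-corrected pooled level
      of the matched BS table): ``t = 1 - (q_C - s*a - r*(1-a)) / a``.

    ``t`` is a derived (not directly binomial) quantity, so its CI comes
    from first-order error propagation over the four binomial inputs.
    Raises :class:`CalibrationError` when ``a <= r`` (no hmC signal above the
    conversion error floor — ``t`` unidentifiable).
    """
    if "assay" in spikein_tab.columns:
        tab = spikein_tab[spikein_tab["assay"] != "BS"]
    else:
        tab = spikein_tab
    cls = context_class(tab["context"])

    un = tab[tab["chrom"] == unmeth_contig]
    if un.empty:
        raise CalibrationError(f"unmethylated contig {unmeth_contig!r} absent from TAB table")
    r_est = _pooled_rate(float(un["mc_count"].sum()), float(un["total_count"].sum()))

    me = tab[(tab["chrom"] == meth_contig) & (cls == "CG")]
    if me.empty:
        raise CalibrationError(f"methylated contig {meth_contig!r} has no CG coverage")
    s_est = _pooled_rate(float(me["mc_count"].sum()), float(me["total_count"].sum()))

    hm = tab[(tab["chrom"] == hmc_contig) & (cls == "CG")]
    if hm.empty:
        raise CalibrationError(f"hmC contig {hmc_contig!r} has no CG coverage")
    q_k, q_n = float(hm["mc_count"].sum()), float(hm["total_count"].sum())
    q_c = q_k / q_n

    cbs = spikein_c_bs[spikein_c_bs["chrom"] == hmc_contig]
    cbs = cbs[context_class(cbs["context"]) == "CG"]
    if cbs.empty or cbs["total_count"].sum() <= 0:
        raise CalibrationError("matched BS table for the hmC contig has no CG coverage")
    a_k, a_n = float(cbs["mc_count"].sum()), float(cbs["total_count"].sum())
    a_raw = a_k / a_n
    a = float(correct_mc_fraction(a_raw, ncr))

    r, s = r_est.rate, s_est.rate
    if a <= r:
        raise CalibrationError(
            f"hmC spike-in abundance a={a:.4f} does not exceed the TAB "
            f"non-conversion rate r={r:.4f}; t is unidentifiable"
        )
    t_hat = 1.0 - (q_c - s * a - r * (1.0 - a)) / a

    # first-order error propagation; t = 1 + s - r - (q - r) / a
    var_q = q_c * (1.0 - q_c) / q_n
    var_a = a_raw * (1.0 - a_raw) / a_n / (1.0 - ncr) ** 2
    var_r = r * (1.0 - r) / r_est.denominator
    var_s = s * (1.0 - s) / s_est.denominator
    d_q = -1.0 / a
    d_a = (q_c - r) / a**2
    d_r = -1.0 + 1.0 / a
    d_s = 1.0
    se_t = float(
        np.sqrt(d_q**2 * var_q + d_a**2 * var_a + d_r**2 * var_r + d_s**2 * var_s)
    )
    t_clamped = float(np.clip(t_hat, 0.0, 1.0))
    lo = float(np.clip(t_hat - 1.96 * se_t, 0.0, 1.0))
    hi = float(np.clip(t_hat + 1.96 * se_t, 0.0, 1.0))
    t_est = RateEstimate(
        t_clamped, q_k, q_n, min(lo, t_clamped), max(hi, t_clamped), method="delta"
    )
    return CalibrationRates(ncr=None, r_tab=r_est, s_tab=s_est, t_tab=t_est)


def estimate_all_rates(
    spikeins: pd.DataFrame,
    unmeth_contig: str = SPIKE_UNMETH,
    meth_contig: str = SPIKE_METH,
    hmc_contig: str = SPIKE_HMC,
) -> CalibrationRates:
    """NCR plus (r, s, t) from a combined spike-in table with an ``assay`` column."""
    if "assay" not in spikeins.columns:
        raise CalibrationError("combined spike-in table needs an 'assay' column")
    bs = spikeins[spikeins["assay"] == "BS"]
    tab = spikeins[spikeins["assay"] == "TAB"]
    ncr = estimate_ncr(bs[bs["chrom"] == unmeth_contig])
    rates = estimate_tab_rates(
        tab,
        bs[bs["chrom"] == hmc_contig],
        ncr=ncr.rate,
        unmeth_contig=unmeth_contig,
        meth_contig=meth_contig,
        hmc_contig=hmc_contig,
    )
    rates.ncr = ncr
    return rates


def correct_table(
    bs: pd.DataFrame,
    tab: pd.DataFrame | None,
    rates: CalibrationRates,
    min_bs_cov: int = 3,
) -> pd.DataFrame:
    """Site-wise corrected (p_mc, p_hmc) from matched BS and TAB tables.

    Joins on (chrom, pos, strand); BS-only sites get ``p_mc`` only; ``p_hmc``
    is withheld (NaN) where TAB coverage is absent or BS coverage is below
    ``min_bs_cov`` (no imputation).  Conflicting contexts at a shared
    coordinate are a hard error.  Join and clamp tallies are logged and
    attached as ``df.attrs``.
    """
    ncr = _rate_value(rates.ncr) if rates.ncr is not None else 0.0
    keys = ["chrom", "pos", "strand"]
    left = bs[keys + ["context", "mc_count", "total_count"]].rename(
        columns={"mc_count": "bs_mc", "total_count": "bs_cov"}
    )
    if tab is None or tab.empty:
        merged = left.copy()
        merged["tab_mc"] = np.nan
        merged["tab_cov"] = 0.0
        n_joined = 0
    else:
        right = tab[keys + ["context", "mc_count", "total_count"]].rename(
            columns={
                "mc_count": "tab_mc",
                "total_count": "tab_cov",
                "context": "context_tab",
            }
        )
        merged = left.merge(right, on=keys, how="left")
        both = merged["context_tab"].notna()
        bad = both & (merged["context"] != merged["context_tab"])
        if bad.any():
            row = merged[bad].iloc[0]
            raise CalibrationError(
                "conflicting trinucleotide contexts at "
                f"{row['chrom']}:{row['pos']}({row['strand']}): "
                f"{row['context']} (BS) vs {row['context_tab']} (TAB)"
            )
        n_joined = int(both.sum())
        merged = merged.drop(columns=["context_tab"])
        merged["tab_cov"] = merged["tab_cov"].fillna(0.0)
    if n_joined == 0 and tab is not None and not tab.empty:
        warnings.warn("BS and TAB tables share no coordinates; no p_hmc computed")

    covered = merged["bs_cov"] > 0
    raw = np.where(covered, merged["bs_mc"] / merged["bs_cov"].where(covered, 1), np.nan)
    p_mc = np.full(len(merged), np.nan)
    p_mc[covered.to_numpy()] = correct_mc_fraction(raw[covered.to_numpy()], ncr)

    usable = (
        covered
        & (merged["bs_cov"] >= min_bs_cov)
        & (merged["tab_cov"] > 0)
        & merged["tab_mc"].notna()
    ).to_numpy()
    p_hmc = np.full(len(merged), np.nan)
    if usable.any():
        q = merged.loc[usable, "tab_mc"].to_numpy() / merged.loc[usable, "tab_cov"].to_numpy()
        p_hmc[usable] = correct_hmc(q, p_mc[usable], rates)

    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "strand": merged["strand"],
            "context": merged["context"],
            "raw_frac": raw,
            "p_mc": p_mc,
            "p_hmc": p_hmc,
            "bs_cov": merged["bs_cov"],
            "tab_cov": merged["tab_cov"],
        }
    )
    with np.errstate(invalid="ignore"):
        n_clamped = int(
            np.nansum((np.asarray(raw) - ncr) / (1.0 - ncr) < -1e-12)
            + np.nansum(np.asarray(raw) > 1.0)
        )
    out.attrs.update(
        n_joined=n_joined,
        n_bs_only=int(len(out) - n_joined),
        n_hmc_withheld=int((~usable).sum()),
        n_clamped_mc=n_clamped,
    )
    logger.info(
        "correct_table: %d sites, %d joined with TAB, %d BS-only, %d p_hmc withheld",
        len(out),
        n_joined,
        len(out) - n_joined,
        out.attrs["n_hmc_withheld"],
    )
    return out


class SpikeInCalibrator(BaseEstimator):
    """Estimator-style wrapper: fit error rates on spike-ins, transform tables.

    ``fit`` consumes a combined spike-in count table (``assay`` column with
    BS and TAB rows, contig names in ``chrom``) and stores the fitted rates
    in ``rates_`` (plus ``ncr_``, ``r_tab_``, ``s_tab_``, ``t_tab_``).
    ``transform`` accepts ``(bs, tab)`` (tab may be None) and returns the
    corrected site table.
    """

    def __init__(
        self,
        min_bs_cov: int = 3,
        unmeth_contig: str = SPIKE_UNMETH,
        meth_contig: str = SPIKE_METH,
        hmc_contig: str = SPIKE_HMC,
    ):
        self.min_bs_cov = min_bs_cov
        self.unmeth_contig = unmeth_contig
        self.meth_contig = meth_contig
        self.hmc_contig = hmc_contig

    def fit(self, X: pd.DataFrame, y=None):
        self.rates_ = estimate_all_rates(
            X,
            unmeth_contig=self.unmeth_contig,
            meth_contig=self.meth_contig,
            hmc_contig=self.hmc_contig,
        )
        self.ncr_ = self.rates_.ncr
        self.r_tab_ = self.rates_.r_tab
        self.s_tab_ = self.rates_.s_tab
        self.t_tab_ = self.rates_.t_tab
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "rates_"):
            raise NotFittedError("SpikeInCalibrator must be fitted before transform")
        if isinstance(X, dict):
            bs, tab = X.get("BS"), X.get("TAB")
        else:
            bs, tab = X
        return correct_table(bs, tab, self.rates_, min_bs_cov=self.min_bs_cov)

    def fit_transform(self, X, y=None, **kwargs):  # spike-ins != target tables
        raise NotImplementedError(
            "fit on spike-ins, then transform the genome-wide tables"
        )
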