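"""Forward simulator for paired bisulfite/TAB methylomes with known truth.

The generator produces every input the analysis stages consume — random
genomes with a cytosine catalog, group-specific methylomes with implanted
differentially methylated regions (DMRs) and region-asymmetric non-CG
methylation, binomial read-count tables for the bisulfite (BS) and
Tet-assisted bisulfite (TAB) assays, spike-in control contigs for error-rate
estimation, and negative-binomial expression matrices with designated
differentially expressed genes — together with a :class:`TruthSet` recording
what was implanted.

Forward model
-------------
Each cytosine site carries a latent state ``(p_mC_only, p_hmC)`` with
``p_mC_only + p_hmC <= 1``; ``p_total = p_mC_only + p_hmC`` is the fraction
of molecules carrying either mark.  Observed counts are binomial draws from

* BS assay:   ``p_read = p_total + (1 - p_total) * ncr``
  (both mC and hmC resist conversion; unmethylated C fails conversion at the
  non-conversion rate ``ncr``), and
* TAB assay:  ``q = (1 - t) * p_hmC + s * p_total + r * (1 - p_total)``
  with ``r`` the bisulfite non-conversion, ``s`` the non-oxidation and ``t``
  the non-protection rate of the TAB protocol.

Coverage per site is Poisson with mean ``coverage_mean``, truncated at 1.
The calibration stage's corrections are the exact algebraic inverses of
these two expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimulatedDataset",
    "SimulationError",
    "simulate_genome",
    "cytosine_catalog",
    "simulate_methylome",
    "simulate_bs_counts",
    "simulate_tab_counts",
    "simulate_spikeins",
    "simulate_expression",
    "simulate_genes",
    "place_uniform_intervals",
    "simulate_dataset",
    "tab_unconverted_fraction",
    "GROUPS",
    "SPIKE_UNMETH",
    "SPIKE_METH",
    "SPIKE_HMC",
]

GROUPS = ("dorsal_SH", "dorsal_EE", "ventral_SH", "ventral_EE")

#: Spike-in contig names: fully unmethylated (lambda-like), fully
#: CG-methylated (lambda + CpG methylase-like), and hydroxymethylated with
#: configurable purity (pUC19-like).
SPIKE_UNMETH = "spike_lambda_unmeth"
SPIKE_METH = "spike_lambda_mCG"
SPIKE_HMC = "spike_puc19_hmC"

_BASES = np.array(list("ACGTN"))
_A, _C, _G, _T, _N = 0, 1, 2, 3, 4
_COMP = np.array([_T, _G, _C, _A, _N])


class SimulationError(ValueError):
    """Invalid simulation configuration or model misuse."""


@dataclass
class SimConfig:
    """All knobs of the forward model.

    Sizes are desk-scale by default; probabilities are fractions in [0, 1].
    ``genome_size`` is bp per chromosome.
    """

    # genome / annotation
    genome_size: int = 100_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.42
    n_genes: int = 30
    gene_length_bp: int = 3_000
    # expression
    n_de_genes: int = 6
    de_log2fc: float = 1.0
    nb_dispersion: float = 0.01
    expr_mean: float = 200.0
    expr_sigma: float = 1.0
    library_size_sd: float = 0.15
    xist_contamination: bool = False
    # methylome
    n_dmrs: int = 20
    dmr_mean_diff: float = 0.26
    dmr_diff_sd: float = 0.045
    dmr_length_bp: int = 1_000
    dmr_dorsal_hypo_frac: float = 0.97
    baseline_mcg: float = 0.75
    mch_dorsal: float = 0.02
    mch_ventral: float = 0.04
    hmcg_level: float = 0.15
    beta_concentration: float = 30.0
    allow_ch_hmc: bool = False
    ee_mcg_effect: float = 0.0
    # assays
    coverage_mean: float = 15.0
    ncr_true: float = 0.005
    r_true: float = 0.003
    s_true: float = 0.02
    t_true: float = 0.08
    # spike-ins
    hmc_spike_purity: float = 0.9
    spikein_length: int = 6_000
    spikein_coverage: float = 30.0
    # design
    n_replicates: int = 5
    seed: int = 0

    _PROBS = (
        "gc_fraction",
        "dmr_mean_diff",
        "dmr_dorsal_hypo_frac",
        "baseline_mcg",
        "mch_dorsal",
        "mch_ventral",
        "hmcg_level",
        "ee_mcg_effect",
        "ncr_true",
        "r_true",
        "s_true",
        "t_true",
        "hmc_spike_purity",
    )

    def validate(self) -> None:
        for name in self._PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v!r} must lie in [0, 1]")
        if self.coverage_mean <= 0 or self.spikein_coverage <= 0:
            raise SimulationError("coverage_mean must be positive")
        if self.n_chromosomes < 1 or self.genome_size < 1_000:
            raise SimulationError("need at least one chromosome of >=1 kb")
        if self.dmr_length_bp >= self.genome_size:
            raise SimulationError("dmr_length_bp must be smaller than genome_size")
        total = self.genome_size * self.n_chromosomes
        if self.n_dmrs * self.dmr_length_bp > 0.5 * total:
            raise SimulationError(
                "genome too small to host the requested DMRs: "
                f"{self.n_dmrs} x {self.dmr_length_bp} bp on {total} bp"
            )
        if self.n_genes * self.gene_length_bp > 0.8 * total:
            raise SimulationError(
                "genome too small to host the requested genes: "
                f"{self.n_genes} x {self.gene_length_bp} bp on {total} bp"
            )
        if self.n_de_genes > self.n_genes:
            raise SimulationError("n_de_genes cannot exceed n_genes")

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.genome_size for i in range(self.n_chromosomes)}


@dataclass
class TruthSet:
    """Ground truth recorded while simulating: what the pipeline must recover."""

    dmrs: pd.DataFrame
    de_genes: pd.DataFrame
    rates: dict[str, float]
    site_state: dict[str, pd.DataFrame] = field(default_factory=dict)
    contaminated_sample: str | None = None

    def to_dict(self) -> dict:
        return {
            "dmrs": self.dmrs.to_dict(orient="records"),
            "de_genes": self.de_genes.to_dict(orient="records"),
            "rates": {k: float(v) for k, v in self.rates.items()},
            "contaminated_sample": self.contaminated_sample,
        }


# ---------------------------------------------------------------------------
# genome and cytosine catalog


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=n, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, _N, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _catalog_one(chrom: str, codes: np.ndarray) -> pd.DataFrame:
    n = len(codes)
    padded = np.concatenate([[_N, _N], codes, [_N, _N]])

    def trimer(first, second, third):
        a = _BASES[first].astype("U1")
        return np.char.add(np.char.add(a, _BASES[second]), _BASES[third])

    # plus strand: C at i, context read forward
    cpos = np.flatnonzero(codes == _C)
    nxt1 = padded[cpos + 3]
    nxt2 = padded[cpos + 4]
    keep = nxt1 != _N  # context class undefined at the chromosome edge
    cpos, nxt1, nxt2 = cpos[keep], nxt1[keep], nxt2[keep]
    plus = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": cpos + 1,  # 1-based
            "strand": "+",
            "context": trimer(np.full(len(cpos), _C), nxt1, nxt2),
        }
    )

    # minus strand: G at i pairs a C; context read along the reverse complement
    gpos = np.flatnonzero(codes == _G)
    prv1 = _COMP[padded[gpos + 1]]
    prv2 = _COMP[padded[gpos + 0]]
    keep = prv1 != _N
    gpos, prv1, prv2 = gpos[keep], prv1[keep], prv2[keep]
    minus = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": gpos + 1,
            "strand": "-",
            "context": trimer(np.full(len(gpos), _C), prv1, prv2),
        }
    )

    out = pd.concat([plus, minus], ignore_index=True)
    out = out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)
    return out


def context_class(context: pd.Series) -> pd.Series:
    """Collapse trinucleotide contexts to {CG, CA, CC, CT}; others -> 'CN'."""
    second = context.str[1]
    cls = "C" + second
    cls = cls.where(second.isin(list("ACGT")), "CN")
    return cls.astype("category")


def cytosine_catalog(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Catalog every cytosine on both strands with its trinucleotide context.

    Positions are 1-based; minus-strand contexts are read from the reverse
    complement.  Cytosines whose immediate 3' neighbour falls off the
    chromosome are dropped (their CG/CH class is undefined).
    """
    frames = [_catalog_one(chrom, _seq_to_codes(seq)) for chrom, seq in seqs.items()]
    cat = pd.concat(frames, ignore_index=True)
    cat["context_class"] = context_class(cat["context"])
    return cat


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw i.i.d. genome sequences and return ``(seqs, catalog)``."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    seqs = {
        chrom: _codes_to_str(_random_codes(rng, size, config.gc_fraction))
        for chrom, size in config.chrom_sizes().items()
    }
    return seqs, cytosine_catalog(seqs)


# ---------------------------------------------------------------------------
# intervals: genes and DMRs


def place_uniform_intervals(
    chrom_sizes: Mapping[str, int],
    n: int,
    lengths,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Place ``n`` non-overlapping intervals uniformly; 0-based half-open."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.ndim == 0:
        lengths = np.full(n, int(lengths))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for i in range(n):
        length = int(lengths[i])
        for _ in range(max_tries):
            ci = int(rng.integers(len(chroms)))
            if sizes[ci] <= length:
                continue
            start = int(rng.integers(0, sizes[ci] - length))
            end = start + length
            if all(end <= s or start >= e for s, e in placed[chroms[ci]]):
                placed[chroms[ci]].append((start, end))
                rows.append((chroms[ci], start, end))
                break
        else:
            raise SimulationError(
                f"could not place interval {i + 1}/{n} of {length} bp; genome too crowded"
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_genes(
    chrom_sizes: Mapping[str, int],
    n_genes: int,
    rng: np.random.Generator,
    gene_length_bp: int = 3_000,
) -> pd.DataFrame:
    """Gene bodies with random strand; TSS is the strand-aware first base."""
    genes = place_uniform_intervals(chrom_sizes, n_genes, gene_length_bp, rng)
    genes["name"] = [f"gene_{i:04d}" for i in range(len(genes))]
    genes["score"] = 0
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)
    return genes


# ---------------------------------------------------------------------------
# methylome


def _beta_around(
    rng: np.random.Generator, mean, conc: float, size: int
) -> np.ndarray:
    """Beta draws with given mean and concentration; degenerate at 0/1."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    out = np.empty(size)
    lo = mean <= 0.0
    hi = mean >= 1.0
    mid = ~(lo | hi)
    out[lo] = 0.0
    out[hi] = 1.0
    if mid.any():
        m = mean[mid]
        out[mid] = rng.beta(m * conc, (1.0 - m) * conc)
    return out


def _interval_index(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Map 0-based positions to the index of a containing sorted,
    non-overlapping interval, or -1."""
    idx = np.searchsorted(starts, pos0, side="right") - 1
    ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
    return np.where(ok, idx, -1)


def simulate_methylome(
    catalog: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    dmrs: pd.DataFrame | None = None,
):
    """Latent per-site methylation states for the four region x condition groups.

    Returns ``(state, dmr_truth)`` where ``state`` maps each group to a frame
    with columns ``p_mc_only`` and ``p_hmc`` aligned to ``catalog``.  CG sites
    share a per-site base level (beta noise around ``baseline_mcg``); inside a
    dorsal-hypomethylated DMR the dorsal total is lowered by the DMR's drawn
    difference (and vice versa).  CH sites get region-specific levels; hmC is
    placed only at CG sites unless ``allow_ch_hmc``.
    """
    if catalog.empty:
        raise SimulationError("cytosine catalog is empty")
    n = len(catalog)
    is_cg = (catalog["context_class"] == "CG").to_numpy()
    is_ch = (catalog["context_class"].isin(["CA", "CC", "CT"])).to_numpy()
    conc = config.beta_concentration

    if dmrs is None:
        if config.n_dmrs > 0:
            lengths = np.maximum(
                50,
                rng.gamma(4.0, config.dmr_length_bp / 4.0, config.n_dmrs).astype(int),
            )
            dmrs = place_uniform_intervals(config.chrom_sizes(), config.n_dmrs, lengths, rng)
        else:
            dmrs = pd.DataFrame(columns=["chrom", "start", "end"])
        direction = np.where(
            rng.random(len(dmrs)) < config.dmr_dorsal_hypo_frac,
            "dorsal_hypo",
            "ventral_hypo",
        )
        dmrs = dmrs.assign(direction=direction)
    dmrs = dmrs.reset_index(drop=True)
    if config.dmr_mean_diff > 0 and len(dmrs):
        deltas = np.clip(
            rng.normal(config.dmr_mean_diff, config.dmr_diff_sd, len(dmrs)), 0.0, 1.0
        )
    else:
        deltas = np.zeros(len(dmrs))
    dmrs = dmrs.assign(delta=deltas)

    base = np.zeros(n)
    base[is_cg] = _beta_around(rng, config.baseline_mcg, conc, int(is_cg.sum()))
    hm = np.zeros(n)
    if config.hmcg_level > 0:
        hm[is_cg] = _beta_around(rng, config.hmcg_level, conc, int(is_cg.sum()))
    if config.allow_ch_hmc and config.hmcg_level > 0:
        hm[is_ch] = _beta_around(rng, config.hmcg_level, conc, int(is_ch.sum()))

    # map sites to DMRs (per chromosome; implanted intervals never overlap)
    site_delta = {"dorsal": np.zeros(n), "ventral": np.zeros(n)}
    clipped = np.zeros(len(dmrs), dtype=bool)
    realized = np.full(len(dmrs), np.nan)
    pos0_all = catalog["pos"].to_numpy() - 1
    site_dmr = np.full(n, -1)
    for chrom, sub in dmrs.groupby("chrom", sort=False):
        mask = (catalog["chrom"] == chrom).to_numpy()
        idx = _interval_index(
            pos0_all[mask], sub["start"].to_numpy(), sub["end"].to_numpy()
        )
        site_dmr[np.flatnonzero(mask)] = np.where(idx >= 0, sub.index.to_numpy()[idx], -1)
    in_dmr = site_dmr >= 0
    if in_dmr.any():
        d_dir = dmrs["direction"].to_numpy()
        d_delta = dmrs["delta"].to_numpy()
        sel = np.flatnonzero(in_dmr & is_cg)
        which = site_dmr[sel]
        hypo_region = np.where(d_dir[which] == "dorsal_hypo", 0, 1)  # 0=dorsal
        for ri, region in enumerate(("dorsal", "ventral")):
            rows = sel[hypo_region == ri]
            site_delta[region][rows] = d_delta[site_dmr[rows]]
        # clip bookkeeping
        under = base - np.maximum(site_delta["dorsal"], site_delta["ventral"]) < 0
        for di in np.unique(site_dmr[sel]):
            drows = sel[site_dmr[sel] == di]
            clipped[di] = bool(under[drows].any())

    ch_level = {"dorsal": config.mch_dorsal, "ventral": config.mch_ventral}
    state: dict[str, pd.DataFrame] = {}
    p_total_region: dict[str, np.ndarray] = {}
    for group in GROUPS:
        region, condition = group.split("_")
        p_total = base.copy()
        delta = site_delta[region].copy()
        if condition == "EE" and region == "dorsal" and config.ee_mcg_effect > 0:
            delta = delta + np.where(site_delta["dorsal"] > 0, config.ee_mcg_effect, 0.0)
        p_total = np.clip(p_total - delta, 0.0, 1.0)
        if group.endswith("SH"):
            p_total_region[region] = p_total
        ch = _beta_around(rng, ch_level[region], conc, n)
        p_total[is_ch] = ch[is_ch]
        p_hmc = np.minimum(hm, p_total)
        if not config.allow_ch_hmc:
            p_hmc[~is_cg] = 0.0
        state[group] = pd.DataFrame(
            {"p_mc_only": p_total - p_hmc, "p_hmc": p_hmc}, index=catalog.index
        )

    for di in range(len(dmrs)):
        rows = np.flatnonzero((site_dmr == di) & is_cg)
        if len(rows):
            realized[di] = float(
                np.mean(p_total_region["dorsal"][rows] - p_total_region["ventral"][rows])
            )
    dmr_truth = dmrs.assign(realized_diff_dv=realized, clipped=clipped)
    return state, dmr_truth


# ---------------------------------------------------------------------------
# read counts


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    c = rng.poisson(lam, size)
    for _ in range(1000):
        zero = c == 0
        if not zero.any():
            break
        c[zero] = rng.poisson(lam, int(zero.sum()))
    c[c == 0] = 1
    return c


def tab_unconverted_fraction(p_hmc, p_total, r: float, s: float, t: float):
    """Expected unconverted-read fraction in the TAB assay (forward model)."""
    p_hmc = np.asarray(p_hmc, dtype=float)
    p_total = np.asarray(p_total, dtype=float)
    return (1.0 - t) * p_hmc + s * p_total + r * (1.0 - p_total)


def _counts_frame(catalog, cov, mc, assay, sample):
    return pd.DataFrame(
        {
            "chrom": catalog["chrom"].to_numpy(),
            "pos": catalog["pos"].to_numpy(),
            "strand": catalog["strand"].to_numpy(),
            "context": catalog["context"].to_numpy(),
            "mc_count": mc,
            "total_count": cov,
            "assay": assay,
            "sample": sample,
        }
    )


def simulate_bs_counts(
    catalog: pd.DataFrame,
    state: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    sample: str = "sample",
    coverage_mean: float | None = None,
) -> pd.DataFrame:
    """Bisulfite read counts: both mC and hmC read as methylated."""
    lam = coverage_mean if coverage_mean is not None else config.coverage_mean
    p_total = (state["p_mc_only"] + state["p_hmc"]).to_numpy()
    p_read = p_total + (1.0 - p_total) * config.ncr_true
    cov = _truncated_poisson(rng, lam, len(catalog))
    mc = rng.binomial(cov, p_read)
    return _counts_frame(catalog, cov, mc, "BS", sample)


def simulate_tab_counts(
    catalog: pd.DataFrame,
    state: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    sample: str = "sample",
    coverage_mean: float | None = None,
) -> pd.DataFrame:
    """TAB read counts: only (protected) hmC survives conversion, plus error terms."""
    lam = coverage_mean if coverage_mean is not None else config.coverage_mean
    p_total = (state["p_mc_only"] + state["p_hmc"]).to_numpy()
    q = tab_unconverted_fraction(
        state["p_hmc"].to_numpy(), p_total, config.r_true, config.s_true, config.t_true
    )
    if (q < -1e-12).any() or (q > 1.0 + 1e-12).any():
        raise SimulationError(
            "TAB forward model produced an unconverted fraction outside [0, 1]; "
            "check the error rates (model misuse)"
        )
    q = np.clip(q, 0.0, 1.0)
    cov = _truncated_poisson(rng, lam, len(catalog))
    mc = rng.binomial(cov, q)
    return _counts_frame(catalog, cov, mc, "TAB", sample)


def simulate_spikeins(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """BS and TAB count tables for the three control contigs.

    * ``SPIKE_UNMETH``: fully unmethylated, all contexts (NCR and r_TAB);
    * ``SPIKE_METH``:  fully CG-methylated (s_TAB);
    * ``SPIKE_HMC``:   hmC at CG sites with purity ``hmc_spike_purity``
      (t_TAB); its matched BS table measures the actual hmC abundance.
    """
    rng = rng or np.random.default_rng(config.seed)
    frames = []
    for contig in (SPIKE_UNMETH, SPIKE_METH, SPIKE_HMC):
        codes = _random_codes(rng, config.spikein_length, config.gc_fraction)
        cat = _catalog_one(contig, codes)
        cat["context_class"] = context_class(cat["context"])
        is_cg = (cat["context_class"] == "CG").to_numpy()
        p_mc_only = np.zeros(len(cat))
        p_hmc = np.zeros(len(cat))
        if contig == SPIKE_METH:
            p_mc_only[is_cg] = 1.0
        elif contig == SPIKE_HMC:
            p_hmc[is_cg] = config.hmc_spike_purity
        st = pd.DataFrame({"p_mc_only": p_mc_only, "p_hmc": p_hmc}, index=cat.index)
        for fn in (simulate_bs_counts, simulate_tab_counts):
            frames.append(
                fn(cat, st, config, rng, sample="spikein", coverage_mean=config.spikein_coverage)
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gene_names: Sequence[str] | None = None,
    de_target_cell: str = "dorsal_EE",
):
    """Negative-binomial count matrix over the 2x2 (region x condition) design.

    ``n_de_genes`` randomly chosen genes get ``de_log2fc`` applied (sign
    alternating up/down) to the ``de_target_cell`` samples.  When
    ``xist_contamination`` is set, an ``Xist`` marker gene is appended and
    one SH sample is given a contaminating high level to exercise QC.

    Returns ``(counts, samples, de_truth)``.
    """
    if config.n_replicates < 2:
        raise SimulationError("need at least 2 replicates per group")
    rng = rng or np.random.default_rng(config.seed)
    if gene_names is None:
        gene_names = [f"gene_{i:04d}" for i in range(config.n_genes)]
    gene_names = list(gene_names)
    n_genes = len(gene_names)

    samples = []
    for region in ("dorsal", "ventral"):
        for condition in ("SH", "EE"):
            for r in range(config.n_replicates):
                samples.append(
                    {
                        "sample": f"{region}_{condition}_r{r + 1}",
                        "region": region,
                        "condition": condition,
                        "pool": f"pool{r + 1}",
                    }
                )
    samples = pd.DataFrame(samples).set_index("sample", drop=False)

    mu = rng.lognormal(np.log(config.expr_mean), config.expr_sigma, n_genes)
    de_idx = rng.choice(n_genes, size=config.n_de_genes, replace=False)
    signs = np.where(np.arange(config.n_de_genes) % 2 == 0, 1.0, -1.0)
    de_truth = pd.DataFrame(
        {
            "gene": [gene_names[i] for i in de_idx],
            "log2fc": signs * config.de_log2fc,
            "target_cell": de_target_cell,
        }
    )

    mu_mat = np.tile(mu[:, None], (1, len(samples)))
    cell = samples["region"] + "_" + samples["condition"]
    target_cols = np.flatnonzero((cell == de_target_cell).to_numpy())
    if config.n_de_genes and len(target_cols) == 0:
        raise SimulationError(f"unknown DE target cell {de_target_cell!r}")
    for i, g in enumerate(de_idx):
        mu_mat[g, target_cols] *= 2.0 ** (signs[i] * config.de_log2fc)
    lib = rng.lognormal(0.0, config.library_size_sd, len(samples))
    mu_mat = mu_mat * lib[None, :]

    phi = config.nb_dispersion
    if phi > 1e-8:
        r_nb = 1.0 / phi
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_mat))
    else:
        counts = rng.poisson(mu_mat)
    counts = pd.DataFrame(counts, index=gene_names, columns=samples.index)

    contaminated = None
    if config.xist_contamination:
        xist_mu = np.full(len(samples), 0.2)
        sh_cols = np.flatnonzero((samples["condition"] == "SH").to_numpy())
        contaminated = samples.index[sh_cols[0]]
        xist_mu[sh_cols[0]] = 5_000.0
        counts.loc["Xist"] = rng.poisson(xist_mu * lib)
    return counts, samples, de_truth, contaminated


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    config: SimConfig
    genomes: dict[str, str]
    catalog: pd.DataFrame
    genes: pd.DataFrame
    truth: TruthSet
    bs_tables: dict[str, list[pd.DataFrame]]
    tab_tables: dict[str, list[pd.DataFrame]]
    spikeins: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame


def simulate_dataset(config: SimConfig, with_tab: bool = True) -> SimulatedDataset:
    """Run the full forward model; deterministic in ``config.seed``.

    Stage-specific generators are spawned from one seed sequence in a fixed
    order so that identical configs give byte-identical outputs.
    """
    config.validate()
    kids = np.random.SeedSequence(config.seed).spawn(6)
    rngs = {
        name: np.random.default_rng(kid)
        for name, kid in zip(
            ("genome", "methylome", "bs", "tab", "spike", "expr"), kids
        )
    }
    genomes, catalog = simulate_genome(config, rngs["genome"])
    genes = simulate_genes(
        config.chrom_sizes(), config.n_genes, rngs["genome"], config.gene_length_bp
    )
    state, dmr_truth = simulate_methylome(catalog, config, rngs["methylome"])

    bs_tables: dict[str, list[pd.DataFrame]] = {}
    tab_tables: dict[str, list[pd.DataFrame]] = {}
    for group in GROUPS:
        bs_tables[group] = [
            simulate_bs_counts(
                catalog, state[group], config, rngs["bs"], sample=f"{group}_r{r + 1}"
            )
            for r in range(config.n_replicates)
        ]
        if with_tab:
            tab_tables[group] = [
                simulate_tab_counts(
                    catalog, state[group], config, rngs["tab"], sample=f"{group}_r{r + 1}"
                )
                for r in range(config.n_replicates)
            ]
    spikeins = simulate_spikeins(config, rngs["spike"])
    counts, samples, de_truth, contaminated = simulate_expression(
        config, rngs["expr"], gene_names=genes["name"]
    )
    truth = TruthSet(
        dmrs=dmr_truth,
        de_genes=de_truth,
        rates={
            "ncr": config.ncr_true,
            "r": config.r_true,
            "s": config.s_true,
            "t": config.t_true,
        },
        site_state=state,
        contaminated_sample=contaminated,
    )
    return SimulatedDataset(
        config=config,
        genomes=genomes,
        catalog=catalog,
        genes=genes,
        truth=truth,
        bs_tables=bs_tables,
        tab_tables=tab_tables,
        spikeins=spikeins,
        counts=counts,
        samples=samples,
    )


def simulate_region_comparison(
    config: SimConfig,
    context: str = "CG",
    groups: tuple[str, str] = ("dorsal_SH", "ventral_SH"),
):
    """BS replicate tables for a two-group comparison, restricted to one context.

    A lean path for DMR-recovery experiments: simulates the genome and
    methylome, keeps only ``context`` sites, and draws BS counts for the two
    requested groups.  Returns ``(catalog, dmr_truth, tables)`` with
    ``tables`` mapping each group to its replicate count tables.
    Deterministic in ``config.seed``.
    """
    config.validate()
    kids = np.random.SeedSequence(config.seed).spawn(3)
    rng_genome, rng_meth, rng_bs = (np.random.default_rng(k) for k in kids)
    _, catalog = simulate_genome(config, rng_genome)
    if context is not None:
        catalog = catalog[catalog["context_class"] == context].reset_index(drop=True)
    state, dmr_truth = simulate_methylome(catalog, config, rng_meth)
    tables = {
        group: [
            simulate_bs_counts(
                catalog, state[group], config, rng_bs, sample=f"{group}_r{r + 1}"
            )
            for r in range(config.n_replicates)
        ]
        for group in groups
    }
    return catalog, dmr_truth, tables


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset to disk in the package's text formats."""
    from pathlib import Path

    from . import io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_fasta(ds.genomes, out / "genome.fa")
    io.write_allc(ds.catalog, out / "cytosine_catalog.tsv")
    io.write_genes_bed12(ds.genes, out / "genes.bed12")
    for group, tables in ds.bs_tables.items():
        for i, t in enumerate(tables):
            io.write_allc(t, out / f"bs_{group}_r{i + 1}.tsv")
    for group, tables in ds.tab_tables.items():
        for i, t in enumerate(tables):
            io.write_allc(t, out / f"tab_{group}_r{i + 1}.tsv")
    io.write_allc(ds.spikeins, out / "spikeins.tsv")
    io.write_counts(ds.counts, out / "expression_counts.tsv")
    io.write_sample_sheet(ds.samples, out / "samples.tsv")
    truth_dmrs = ds.truth.dmrs.copy()
    io.write_bed(
        truth_dmrs.assign(name=[f"true_dmr_{i}" for i in range(len(truth_dmrs))]),
        out / "true_dmrs.bed",
        columns=["chrom", "start", "end", "name", "delta", "direction"],
    )
    io.write_json(ds.truth.to_dict(), out / "truth.json")
    io.dump_config(ds.config, out / "config.yaml")
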