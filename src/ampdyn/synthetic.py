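"""Synthetic community time series with region-specific primer bias.

The generator emulates the statistical structure of a year-long monthly
survey of an activated-sludge basin sequenced with two 16S rRNA primer
pairs: a dominant temporally stable core holding about two thirds of total
abundance, transient rare taxa occupying random sub-windows of the series,
a seasonal temperature covariate that mildly drives composition, a bloom
taxon (the filamentous-bulking case) with strongly region-dependent
amplification, and multinomial sequencing noise at a fixed per-sample depth.

The causal claim the generator encodes: both "regions" observe the SAME
latent community series; they differ only in a multiplicative per-taxon
bias vector applied before multinomial read sampling.  Presence/absence is
untouched by any strictly positive bias, so compositional detail diverges
between regions while community dynamics do not.

Latent dynamics are an AR(1) walk on log abundance — the simplest
stationary autocorrelated positive process; it is a stand-in with stated
parameters, not an inferred model of activated sludge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .fish import FOVPair
from .io_formats import CommunityTable, PhyloTree, TimeSeriesDesign

logger = logging.getLogger("ampdyn")

DEFAULT_REGIONS = ("V1V3", "V4")


@dataclass
class BloomSpec:
    """A core taxon that blooms at stated time points and is preferentially
    amplified by one primer region.

    The bloom is an additive Gaussian bump on the latent log scale at each
    peak time point, with the bump amplitude solved so the taxon's true
    relative abundance at the peak equals ``peak_rel_abund``."""

    taxon: int = 0  # index into the taxon list (must be a core taxon)
    peak_times: tuple[int, ...] = (2, 11)  # months, 1-based
    peak_rel_abund: float = 0.005  # true relative abundance at each peak
    baseline_rel_abund: float = 0.001  # typical off-peak true relative abundance
    width: float = 0.75  # Gaussian bump width, months
    region_bias: dict[str, float] = field(
        default_factory=lambda: {"V1V3": 12.0, "V4": 1.0}
    )


@dataclass
class TemperatureModel:
    """Sinusoidal basin temperature.  Defaults put month 1 in austral autumn
    with winter lows below 18 °C and summer highs above 26 °C."""

    mean: float = 22.0  # °C
    amplitude: float = 5.0  # °C
    peak_month: float = 9.0  # warmest time point (1-based)

    def series(self, T: int) -> np.ndarray:
        t = np.arange(1, T + 1)
        return self.mean + self.amplitude * np.cos(
            2.0 * np.pi * (t - self.peak_month) / 12.0
        )


@dataclass
class SyntheticParams:
    n_core: int = 20
    n_transient: int = 80
    T: int = 12  # time points (months)
    R: int = 2  # technical replicates per region
    regions: tuple[str, ...] = DEFAULT_REGIONS
    depth: int = 2125  # reads per sample
    core_fraction: float = 0.66  # target core share of total abundance
    ar_rho: float = 0.9  # AR(1) autocorrelation of log abundance
    ar_sigma: float = 0.12  # AR(1) innovation s.d. (log units)
    season_effect: float = 1.3  # seasonal modulation of innovation s.d.
    #   (community-wide: warm months are more variable than cold ones)
    base_sigma: float = 1.0  # spread of per-taxon base log abundances
    transient_offset: float = -1.0  # transient base log-mean below core
    replicate_sigma: float = 0.40  # PCR-replicate lognormal jitter (log units)
    bias_sigma: float = 0.20  # lognormal s.d. of per-taxon bias factors
    bias: dict[str, np.ndarray] | None = None  # explicit per-region vectors
    temp_effect: float = 1.2  # s.d. of per-taxon temperature sensitivity
    bloom: BloomSpec | None = field(default_factory=BloomSpec)
    temperature: TemperatureModel = field(default_factory=TemperatureModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_transient < 2:
            raise ValueError("need at least 2 taxa")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in [0, 1]")
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.bias is not None:
            for region, b in self.bias.items():
                b = np.asarray(b, dtype=float)
                if (b <= 0).any():
                    raise ValueError(f"bias factors for {region} must all be > 0")

    @property
    def n_taxa(self) -> int:
        return self.n_core + self.n_transient

    @property
    def taxon_ids(self) -> list[str]:
        return [f"OTU{i:04d}" for i in range(self.n_taxa)]


@dataclass
class TrueCommunitySeries:
    """Latent truth: relative abundances (taxa x T, columns on the simplex),
    occupancy mask, and the temperature series."""

    taxon_ids: list[str]
    abundances: np.ndarray  # taxa x T, columns sum to 1
    occupancy: np.ndarray  # taxa x T bool
    temperature: np.ndarray  # T
    n_core: int

    @property
    def T(self) -> int:
        return self.abundances.shape[1]

    @property
    def core_ids(self) -> list[str]:
        return self.taxon_ids[: self.n_core]

    def core_share(self) -> float:
        """Fraction of total abundance (averaged over time) in core taxa."""
        return float(self.abundances[: self.n_core].sum(axis=0).mean())


def generate_true_series(params: SyntheticParams) -> TrueCommunitySeries:
    """Latent community series: AR(1) log-abundance walks around per-taxon
    base levels, a temperature-sensitivity term, optional bloom bumps,
    transient occupancy windows, and a one-off rescaling of the transient
    block so the realized mean core share hits ``core_fraction``."""
    rng = np.random.default_rng(params.seed)
    n, T = params.n_taxa, params.T
    base = rng.normal(0.0, params.base_sigma, size=n)
    base[params.n_core :] += params.transient_offset
    if params.bloom is not None:
        if params.bloom.taxon >= params.n_core:
            raise ValueError("bloom taxon must be a core taxon")
        # pin the bloom's off-peak level at its stated baseline share
        others = np.exp(np.delete(base, params.bloom.taxon)).sum()
        frac = params.bloom.baseline_rel_abund
        base[params.bloom.taxon] = np.log(frac * others / (1.0 - frac))

    temperature = params.temperature.series(T)
    temp_sd = params.temperature.amplitude / np.sqrt(2.0)
    z_temp = (temperature - params.temperature.mean) / temp_sd if temp_sd else np.zeros(T)

    # AR(1) walk, stationary start; the innovation s.d. is modulated by the
    # season so warm months reshuffle the whole community more than cold
    # ones — a community-wide change signal that survives any per-taxon
    # reweighting downstream
    sigma_t = params.ar_sigma * np.clip(1.0 + params.season_effect * z_temp, 0.1, None)
    x = np.zeros((n, T))
    stat_sd = params.ar_sigma / np.sqrt(1.0 - params.ar_rho**2) if params.ar_sigma else 0.0
    x[:, 0] = rng.normal(0.0, stat_sd, size=n) if stat_sd else 0.0
    for t in range(1, T):
        innov = rng.normal(0.0, sigma_t[t], size=n) if params.ar_sigma else 0.0
        x[:, t] = params.ar_rho * x[:, t - 1] + innov

    gamma = rng.normal(0.0, params.temp_effect, size=n) if params.temp_effect else np.zeros(n)

    log_abund = base[:, None] + x + gamma[:, None] * z_temp[None, :]
    abund = np.exp(log_abund)

    # transient taxa live on a random window of length < T
    occupancy = np.ones((n, T), dtype=bool)
    for i in range(params.n_core, n):
        length = int(rng.integers(1, T))  # 1 .. T-1
        start = int(rng.integers(0, T - length + 1))
        mask = np.zeros(T, dtype=bool)
        mask[start : start + length] = True
        occupancy[i] = mask
    abund[~occupancy] = 0.0

    abund = _calibrate_core_share(abund, params.n_core, params.core_fraction)
    if params.bloom is not None:
        abund = _apply_bloom(abund, params.bloom, T)
    totals = abund.sum(axis=0)
    series = TrueCommunitySeries(
        params.taxon_ids, abund / totals, abund > 0, temperature, params.n_core
    )
    return series


def _apply_bloom(abund: np.ndarray, bloom: BloomSpec, T: int) -> np.ndarray:
    """Additive Gaussian bumps on the bloom taxon's latent log abundance,
    one per peak time, each amplitude solved so the taxon's relative
    abundance at that peak equals ``peak_rel_abund``."""
    out = abund.copy()
    t_axis = np.arange(1, T + 1, dtype=float)
    target = bloom.peak_rel_abund
    log_bump = np.zeros(T)
    peaks = [p for p in bloom.peak_times if 1 <= p <= T]
    if len(peaks) < len(bloom.peak_times):
        warnings.warn(f"bloom peak times outside 1..{T} ignored")
    for peak in peaks:
        w_peak = out[bloom.taxon, peak - 1]
        s_other = out[:, peak - 1].sum() - w_peak
        if w_peak <= 0 or s_other <= 0 or not 0 < target < 1:
            continue
        amplitude = np.log(target * s_other / ((1.0 - target) * w_peak))
        log_bump += amplitude * np.exp(-((t_axis - peak) ** 2) / (2.0 * bloom.width**2))
    out[bloom.taxon] *= np.exp(log_bump)
    return out


def _calibrate_core_share(
    abund: np.ndarray, n_core: int, target: float
) -> np.ndarray:
    """Scale the transient block by one scalar so the time-averaged core
    share of total abundance equals ``target`` (best effort when a block is
    empty)."""
    core = abund[:n_core].sum(axis=0)
    trans = abund[n_core:].sum(axis=0) if abund.shape[0] > n_core else np.zeros_like(core)
    if trans.sum() == 0 or core.sum() == 0:
        if not (trans.sum() == 0 and target >= 1.0) and n_core and abund.shape[0] > n_core:
            warnings.warn("core_fraction unreachable; leaving abundances unscaled")
        return abund

    def share(s: float) -> float:
        return float(np.mean(core / (core + s * trans)))

    if target <= 0.0 or target >= 1.0:
        warnings.warn("core_fraction at the boundary; leaving abundances unscaled")
        return abund
    lo, hi = 1e-12, 1e12
    if not (share(hi) <= target <= share(lo)):
        warnings.warn("core_fraction unreachable; best effort")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if share(mid) > target:
            lo = mid
        else:
            hi = mid
    out = abund.copy()
    out[n_core:] *= np.sqrt(lo * hi)
    return out


def apply_primer_bias(
    series: TrueCommunitySeries, bias: np.ndarray
) -> TrueCommunitySeries:
    """Multiplicative amplification bias followed by renormalization:
    p'_i(t) = b_i p_i(t) / sum_j b_j p_j(t).  Zeros stay zero, so any
    strictly positive bias leaves presence/absence untouched."""
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (len(series.taxon_ids),):
        raise ValueError("bias length must equal the number of taxa")
    if (bias <= 0).any():
        raise ValueError("bias factors must all be > 0")
    biased = series.abundances * bias[:, None]
    biased /= biased.sum(axis=0)
    return replace(series, abundances=biased)


def region_bias_vectors(params: SyntheticParams) -> dict[str, np.ndarray]:
    """Per-region bias vectors: explicit ones from ``params.bias`` if given,
    else i.i.d. lognormal(0, bias_sigma) per taxon drawn independently per
    region, with the bloom taxon's region-specific factor multiplied on."""
    out: dict[str, np.ndarray] = {}
    for k, region in enumerate(params.regions):
        if params.bias is not None and region in params.bias:
            b = np.asarray(params.bias[region], dtype=float).copy()
        else:
            rng = np.random.default_rng([params.seed, 101, k])
            b = rng.lognormal(0.0, params.bias_sigma, size=params.n_taxa)
        if params.bloom is not None and (params.bias is None or region not in params.bias):
            # the bloom taxon's bias factor is set exactly, so the stated
            # between-region amplification ratio is realized by construction
            b[params.bloom.taxon] = params.bloom.region_bias.get(region, 1.0)
        out[region] = b
    return out


def sample_reads(
    series: TrueCommunitySeries,
    depth: int,
    R: int,
    seed: int | np.random.Generator,
    region: str = "V1V3",
    covariates: dict[str, np.ndarray] | None = None,
    replicate_sigma: float = 0.15,
) -> tuple[CommunityTable, TimeSeriesDesign]:
    """One multinomial draw of ``depth`` reads per (time point, replicate)
    from the series' simplex columns.  Replicates are technical: each gets
    an independent per-taxon lognormal jitter of s.d. ``replicate_sigma``
    (log units) on top of the shared column — the compositional drift of
    independent PCR reactions — before its multinomial draw, so replicate
    disagreement is not artificially limited to counting noise.  Jitter
    never creates or removes presence.  Temperature (and any extra
    per-time-point covariates) are copied into the design."""
    rng = np.random.default_rng(seed)
    T = series.T
    n = len(series.taxon_ids)
    sample_ids, columns, rows = [], [], []
    for t in range(1, T + 1):
        p = series.abundances[:, t - 1]
        for r in range(1, R + 1):
            if replicate_sigma > 0:
                jitter = np.exp(rng.normal(0.0, replicate_sigma, size=n))
                pr = p * jitter
                pr /= pr.sum()
            else:
                pr = p
            sample_ids.append(f"{region}_t{t:02d}_r{r}")
            columns.append(rng.multinomial(depth, pr))
            row = {"time_point": t, "replicate": r, "region": region,
                   "temperature": float(series.temperature[t - 1])}
            if covariates:
                for name, values in covariates.items():
                    row[name] = float(values[t - 1])
            rows.append(row)
    table = CommunityTable(series.taxon_ids, sample_ids, np.column_stack(columns))
    design = TimeSeriesDesign(pd.DataFrame(rows, index=sample_ids))
    return table, design


def generate_tree(
    taxon_ids: list[str], seed: int | np.random.Generator, mean_length: float = 0.1
) -> PhyloTree:
    """Random rooted binary tree over the taxa by iterative random joins;
    every non-root edge gets an i.i.d. exponential(mean ``mean_length``)
    branch length."""
    if len(taxon_ids) < 2:
        raise ValueError("need >= 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    nodes = [
        TreeNode(name=t, length=float(rng.exponential(mean_length))) for t in taxon_ids
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.exponential(mean_length)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(length=0.0)
    root.extend(nodes)
    return PhyloTree(root)


def operational_covariates(params: SyntheticParams) -> dict[str, np.ndarray]:
    """Plausible activated-sludge plant covariates (MLSS mg/L, SVI mL/g,
    influent BOD mg/L) as smooth noise series; unlike temperature they do
    not drive the community, matching a setting where temperature is the
    only influential variable."""
    rng = np.random.default_rng([params.seed, 202])
    T = params.T

    def ar_series(mean: float, sd: float, rho: float = 0.5) -> np.ndarray:
        x = np.zeros(T)
        x[0] = rng.normal(0, sd)
        for t in range(1, T):
            x[t] = rho * x[t - 1] + rng.normal(0, sd * np.sqrt(1 - rho**2))
        return mean + x

    return {
        "mlss": ar_series(2500.0, 300.0),
        "svi": ar_series(120.0, 25.0),
        "bod": ar_series(200.0, 35.0),
    }


def generate_fish_fovs(
    target_fraction: float,
    n_fov: int = 30,
    noise_sd: float = 0.02,
    image_size: int = 512,
    seed: int | np.random.Generator = 0,
) -> list[FOVPair]:
    """Paired probe/DAPI masks for ``n_fov`` fields of view.

    Each DAPI mask is a union of random disks (floc-like blobs); the probe
    mask is a random subset of DAPI pixels covering the target fraction
    perturbed by a truncated Gaussian of s.d. ``noise_sd`` per FOV, so
    probe ⊆ DAPI by construction.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    fovs = []
    for _ in range(n_fov):
        dapi = np.zeros((image_size, image_size), dtype=bool)
        for _ in range(int(rng.integers(10, 25))):
            cy, cx = rng.uniform(0, image_size, size=2)
            radius = rng.uniform(image_size / 32, image_size / 8)
            dapi |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        n_dapi = int(dapi.sum())
        frac = float(np.clip(rng.normal(target_fraction, noise_sd), 0.0, 1.0)) \
            if noise_sd > 0 else target_fraction
        n_probe = int(round(frac * n_dapi))
        probe = np.zeros_like(dapi)
        if n_probe > 0 and n_dapi > 0:
            flat = np.flatnonzero(dapi)
            chosen = rng.choice(flat, size=min(n_probe, n_dapi), replace=False)
            probe.flat[chosen] = True
        fovs.append(FOVPair(probe, dapi))
    return fovs


@dataclass
class SimulatedExperiment:
    params: SyntheticParams
    true_series: TrueCommunitySeries
    biased_series: dict[str, TrueCommunitySeries]
    bias: dict[str, np.ndarray]
    tables: dict[str, CommunityTable]
    design: TimeSeriesDesign
    tree: PhyloTree


def simulate_experiment(params: SyntheticParams) -> SimulatedExperiment:
    """End-to-end simulation of the two-region design: one latent series,
    per-region bias, multinomial read sampling, a random phylogeny, and a
    combined design table with operational covariates."""
    true_series = generate_true_series(params)
    bias = region_bias_vectors(params)
    covs = operational_covariates(params)
    tables: dict[str, CommunityTable] = {}
    frames = []
    biased: dict[str, TrueCommunitySeries] = {}
    for k, region in enumerate(params.regions):
        biased[region] = apply_primer_bias(true_series, bias[region])
        table, design = sample_reads(
            biased[region], params.depth, params.R,
            np.random.default_rng([params.seed, 303, k]), region, covs,
            replicate_sigma=params.replicate_sigma,
        )
        tables[region] = table
        frames.append(design.frame)
    design = TimeSeriesDesign(pd.concat(frames))
    tree = generate_tree(params.taxon_ids, np.random.default_rng([params.seed, 404]))
    return SimulatedExperiment(params, true_series, biased, bias, tables, design, tree)
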