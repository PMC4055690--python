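"""Temporal community dynamics: core detection, moving-window analysis,
similarity-decay regression, the taxa-time relationship, and the end-to-end
two-region comparison.

Conventions shared by every operation here: time points are 1-based
consecutive months; a taxon is "present" at a time point when its counts
summed over that time point's technical replicates are > 0 (a strict
per-replicate mode is exposed); all time lags are time-point differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta import distance_matrix
from .io_formats import (
    CommunityTable,
    DistanceMatrix,
    PhyloTree,
    TimeSeriesDesign,
    lineage_label,
)
from .ordination import MantelResult, ProcrustesResult, mantel, nmds, procrustes

logger = logging.getLogger("ampdyn")


@dataclass
class CoreSet:
    """Taxa present at every time point of a region's series, with the
    occupancy histogram and the share of total reads they hold."""

    region: str
    taxon_ids: list[str]
    occupancy: pd.Series  # taxon -> number of time points present
    abundance_share: float
    T: int


@dataclass
class STRFit:
    """Power-law fit S = c * T^w of cumulative observed taxa against time;
    w is the taxon replacement rate."""

    c: float
    w: float
    stderr_w: float
    r2: float
    level: str
    replicate: int
    region: str
    cumulative_richness: np.ndarray


@dataclass
class DecayFit:
    """OLS fit of log10(similarity) on time lag within one replicate track."""

    slope: float  # per month, log10 units
    intercept: float
    stderr_slope: float
    p_slope: float
    r2: float
    metric: str
    replicate: int
    region: str
    n_pairs: int
    n_excluded: int


@dataclass
class MovingWindowSeries:
    """Mean community dissimilarity between consecutive time points (all
    replicate pairings), plus SEM, per interval t -> t+1."""

    region: str
    metric: str
    intervals: list[tuple[int, int]]
    means: np.ndarray
    sems: np.ndarray
    single_pair: bool = False  # SEM reported as 0 for one pairing per interval

    @property
    def values(self) -> np.ndarray:
        return self.means


@dataclass
class TwoSampleTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Core detection
# ---------------------------------------------------------------------------


def occupancy_table(
    table: CommunityTable,
    design: TimeSeriesDesign,
    region: str,
    pool_replicates: bool = True,
) -> pd.DataFrame:
    """Presence (bool) of every taxon at every time point of a region.
    ``pool_replicates``: seen in any replicate counts as present; the strict
    alternative requires presence in every replicate."""
    tps = design.time_points
    presence = {}
    for t in tps:
        samples = design.samples_for(region=region, time_point=t)
        if not samples:
            raise ValueError(f"region {region!r} has no samples at time point {t}")
        idx = [table.sample_ids.index(s) for s in samples]
        block = table.counts[:, idx] > 0
        presence[t] = block.any(axis=1) if pool_replicates else block.all(axis=1)
    return pd.DataFrame(presence, index=table.taxon_ids)


def detect_core(
    table: CommunityTable,
    design: TimeSeriesDesign,
    region: str,
    pool_replicates: bool = True,
    min_occupancy: int | None = None,
) -> CoreSet:
    """Core community of a region: taxa present at all T time points (or at
    >= ``min_occupancy`` of them), with the fraction of the region's reads
    they account for."""
    presence = occupancy_table(table, design, region, pool_replicates)
    T = presence.shape[1]
    threshold = T if min_occupancy is None else min_occupancy
    occupancy = presence.sum(axis=1)
    core_ids = [t for t in table.taxon_ids if occupancy[t] >= threshold]
    samples = design.samples_for(region=region)
    idx = [table.sample_ids.index(s) for s in samples]
    total = table.counts[:, idx].sum()
    core_rows = [table.taxon_ids.index(t) for t in core_ids]
    share = float(table.counts[np.ix_(core_rows, idx)].sum() / total) if total else 0.0
    return CoreSet(region, core_ids, occupancy, share, T)


def shared_core(
    core_a: CoreSet,
    core_b: CoreSet,
    taxonomy: pd.DataFrame,
    table_a: CommunityTable,
    table_b: CommunityTable,
    design: TimeSeriesDesign,
) -> pd.DataFrame:
    """Shared core of two regions at the taxonomic rank of order.

    Each region's core taxa are aggregated to order labels (taxa without an
    order get ``unclassified_<deepest classified parent>``); the shared set
    is the orders found in both cores.  Returns per-order mean relative
    abundance per region plus membership flags.
    """

    def order_profile(core: CoreSet, table: CommunityTable) -> pd.Series:
        samples = design.samples_for(region=core.region)
        idx = [table.sample_ids.index(s) for s in samples]
        rel = table.counts[:, idx] / table.counts[:, idx].sum(axis=0)
        mean_rel = rel.mean(axis=1)
        orders: dict[str, float] = {}
        for taxon in core.taxon_ids:
            label = lineage_label(taxonomy, taxon, "order")
            orders[label] = orders.get(label, 0.0) + float(
                mean_rel[table.taxon_ids.index(taxon)]
            )
        return pd.Series(orders)

    prof_a = order_profile(core_a, table_a)
    prof_b = order_profile(core_b, table_b)
    orders = sorted(set(prof_a.index) | set(prof_b.index))
    out = pd.DataFrame(
        {
            f"share_{core_a.region}": prof_a.reindex(orders).fillna(0.0),
            f"share_{core_b.region}": prof_b.reindex(orders).fillna(0.0),
        },
        index=pd.Index(orders, name="order"),
    )
    out["shared"] = (out.iloc[:, 0] > 0) & (out.iloc[:, 1] > 0)
    return out


def shared_core_summary(shared: pd.DataFrame) -> dict[str, float]:
    """Per-region abundance share held by the shared (both-region) orders."""
    mask = shared["shared"]
    return {
        col: float(shared.loc[mask, col].sum())
        for col in shared.columns
        if col.startswith("share_")
    }


# ---------------------------------------------------------------------------
# Moving window
# ---------------------------------------------------------------------------


def moving_window(
    D: DistanceMatrix, design: TimeSeriesDesign, region: str
) -> MovingWindowSeries:
    """Mean dissimilarity between consecutive time points, over all
    replicate pairings (r_i at t) x (r_j at t+1); SEM across those
    pairings (0, flagged, when only one pairing exists)."""
    tps = design.time_points
    intervals, means, sems = [], [], []
    single = False
    for t, t_next in zip(tps[:-1], tps[1:]):
        left = design.samples_for(region=region, time_point=t)
        right = design.samples_for(region=region, time_point=t_next)
        if not left or not right:
            raise ValueError(f"region {region!r} missing samples for interval {t}->{t_next}")
        values = np.array([D.get(a, b) for a in left for b in right])
        intervals.append((t, t_next))
        means.append(values.mean())
        if len(values) > 1:
            sems.append(values.std(ddof=1) / math.sqrt(len(values)))
        else:
            sems.append(0.0)
            single = True
    return MovingWindowSeries(
        region, D.metric, intervals, np.array(means), np.array(sems), single
    )


# ---------------------------------------------------------------------------
# Similarity decay
# ---------------------------------------------------------------------------


def similarity_decay(
    D: DistanceMatrix,
    design: TimeSeriesDesign,
    region: str,
    log_base: float = 10.0,
) -> list[DecayFit]:
    """Per-replicate OLS of log10(1 - distance) on time lag (months).

    Pairs are drawn within a replicate track only, at every lag >= 1; pairs
    whose similarity is <= 0 are excluded (count reported), not floored.
    """
    fits = []
    for rep in design.replicates(region):
        lags, logsim, excluded = [], [], 0
        samples = {
            int(design.frame.loc[s, "time_point"]): s
            for s in design.samples_for(region=region, replicate=rep)
        }
        tps = sorted(samples)
        for i, t1 in enumerate(tps):
            for t2 in tps[i + 1 :]:
                sim = 1.0 - D.get(samples[t1], samples[t2])
                if sim <= 0.0:
                    excluded += 1
                    continue
                lags.append(t2 - t1)
                logsim.append(math.log(sim, log_base))
        if len(lags) < 3 or len(set(lags)) < 3:
            raise ValueError(
                f"replicate {rep} of region {region!r}: need pairs at >= 3 distinct lags"
            )
        res = stats.linregress(lags, logsim)
        fits.append(
            DecayFit(
                slope=float(res.slope),
                intercept=float(res.intercept),
                stderr_slope=float(res.stderr),
                p_slope=float(res.pvalue),
                r2=float(res.rvalue**2),
                metric=D.metric,
                replicate=rep,
                region=region,
                n_pairs=len(lags),
                n_excluded=excluded,
            )
        )
        if excluded:
            logger.info(
                "region %s replicate %d: excluded %d non-positive similarities",
                region, rep, excluded,
            )
    return fits


def compare_slopes(slopes_a: np.ndarray, slopes_b: np.ndarray) -> TwoSampleTestResult:
    """Unpaired two-tailed Student's t with pooled variance;
    df = nA + nB - 2.  Zero pooled variance: p = 1 when the means agree,
    degenerate (p = 0, flagged) when they do not."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 slopes per group")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return TwoSampleTestResult(0.0, df, 1.0, degenerate=True)
        return TwoSampleTestResult(math.inf if diff > 0 else -math.inf, df, 0.0, True)
    t = diff / math.sqrt(pooled * (1.0 / len(a) + 1.0 / len(b)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TwoSampleTestResult(float(t), df, float(p))


# ---------------------------------------------------------------------------
# Taxa-time relationship
# ---------------------------------------------------------------------------


def cumulative_richness(
    table: CommunityTable,
    design: TimeSeriesDesign,
    region: str,
    replicate: int,
    level: str = "otu",
    taxonomy: pd.DataFrame | None = None,
    drop_singletons: bool = True,
) -> np.ndarray:
    """S(t): number of distinct taxa (or genera) observed in time points
    1..t of one replicate track, after removing taxa whose total count over
    the whole track is exactly 1."""
    samples = {
        int(design.frame.loc[s, "time_point"]): s
        for s in design.samples_for(region=region, replicate=replicate)
    }
    tps = sorted(samples)
    idx = [table.sample_ids.index(samples[t]) for t in tps]
    counts = table.counts[:, idx]
    keep = counts.sum(axis=1) != 1 if drop_singletons else np.ones(table.n_taxa, bool)
    counts = counts[keep]
    ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    if level == "genus":
        if taxonomy is None:
            raise ValueError("genus-level STR needs a taxonomy")
        labels = [lineage_label(taxonomy, t, "genus") for t in ids]
        frame = pd.DataFrame(counts, index=labels)
        counts = frame.groupby(level=0).sum().to_numpy()
    elif level != "otu":
        raise ValueError(f"unknown level {level!r}")
    seen = np.zeros(counts.shape[0], dtype=bool)
    S = np.zeros(len(tps), dtype=int)
    for j in range(len(tps)):
        seen |= counts[:, j] > 0
        S[j] = int(seen.sum())
    return S


def fit_power_law(S: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of log10 S on log10 t for t = 1..len(S); returns (c, w,
    stderr_w, r2) with S = c * t^w."""
    S = np.asarray(S, dtype=float)
    if len(S) < 3:
        raise ValueError("need >= 3 time points")
    if S[0] <= 0:
        raise ValueError("S(1) must be > 0")
    t = np.arange(1, len(S) + 1, dtype=float)
    res = stats.linregress(np.log10(t), np.log10(S))
    return 10.0**res.intercept, float(res.slope), float(res.stderr), float(res.rvalue**2)


def taxa_time_relationship(
    table: CommunityTable,
    design: TimeSeriesDesign,
    region: str,
    level: str = "otu",
    taxonomy: pd.DataFrame | None = None,
) -> list[STRFit]:
    """Taxa-time relationship S = c T^w per replicate track of a region.

    New taxa (or genera) are accumulated over the ordered time points,
    whole-series singletons removed first, and the log-log regression gives
    the replacement rate w.  Replicate tracks are fitted independently.
    """
    fits = []
    for rep in design.replicates(region):
        S = cumulative_richness(table, design, region, rep, level, taxonomy)
        c, w, se, r2 = fit_power_law(S)
        fits.append(STRFit(c, w, se, r2, level, rep, region, S))
    return fits


def mean_w(fits: list[STRFit]) -> tuple[float, float]:
    """Across-replicate mean and SEM of the replacement rate w."""
    ws = np.array([f.w for f in fits])
    sem = float(ws.std(ddof=1) / math.sqrt(len(ws))) if len(ws) > 1 else 0.0
    return float(ws.mean()), sem


# ---------------------------------------------------------------------------
# End-to-end two-region comparison
# ---------------------------------------------------------------------------

METRICS = ("bray_curtis", "unifrac_unweighted", "unifrac_weighted")


@dataclass
class RegionComparisonReport:
    regions: tuple[str, str]
    mantel: dict[str, MantelResult]
    procrustes: ProcrustesResult
    nmds_stress: dict[str, float]
    moving_window_r: dict[str, float]
    moving_window: dict[str, dict[str, MovingWindowSeries]]
    decay_fits: dict[str, dict[str, list[DecayFit]]]
    slope_tests: dict[str, TwoSampleTestResult]
    str_fits: dict[str, list[STRFit]]
    w_test: TwoSampleTestResult
    cores: dict[str, CoreSet]
    shared_core_shares: dict[str, float] | None

    def to_dict(self) -> dict:
        out: dict = {"regions": list(self.regions)}
        out["mantel"] = {m: {"r": v.r, "p": v.p} for m, v in self.mantel.items()}
        out["procrustes"] = {
            "m2": self.procrustes.m2,
            "correlation": self.procrustes.correlation,
            "p": self.procrustes.p,
        }
        out["nmds_stress"] = self.nmds_stress
        out["moving_window_pearson_r"] = self.moving_window_r
        out["decay_slopes"] = {
            m: {
                region: [f.slope for f in fits]
                for region, fits in per_region.items()
            }
            for m, per_region in self.decay_fits.items()
        }
        out["decay_slope_tests"] = {
            m: {"t": v.t, "df": v.df, "p": v.p} for m, v in self.slope_tests.items()
        }
        out["str_w"] = {
            region: {"mean": mean_w(fits)[0], "sem": mean_w(fits)[1]}
            for region, fits in self.str_fits.items()
        }
        out["w_test"] = {"t": self.w_test.t, "df": self.w_test.df, "p": self.w_test.p}
        out["core"] = {
            region: {"n_core": len(c.taxon_ids), "abundance_share": c.abundance_share}
            for region, c in self.cores.items()
        }
        if self.shared_core_shares is not None:
            out["shared_core_shares"] = self.shared_core_shares
        return out


def _ordered_samples(design: TimeSeriesDesign, region: str) -> list[str]:
    sub = design.frame[design.frame["region"] == region]
    return list(sub.sort_values(["time_point", "replicate"]).index)


def run_region_comparison(
    table_a: CommunityTable,
    table_b: CommunityTable,
    tree: PhyloTree,
    design: TimeSeriesDesign,
    regions: tuple[str, str] | None = None,
    taxonomy: pd.DataFrame | None = None,
    n_perm: int = 999,
    nmds_starts: int = 8,
    seed: int = 0,
) -> RegionComparisonReport:
    """The full two-region pipeline: per-region distance matrices for three
    metrics, Mantel correlations between matched matrices, NMDS + Procrustes
    of the two ordinations, moving-window profiles and their Pearson
    correlation, per-replicate similarity-decay slopes compared by t-test,
    taxa-time fits with a t-test on w, and core detection (shared core at
    order rank when a taxonomy is supplied).

    Samples of the two regions are matched by (time_point, replicate), so
    both tables must cover the same T x R grid.
    """
    if regions is None:
        regs = design.regions
        if len(regs) != 2:
            raise ValueError("design must contain exactly two regions")
        regions = (regs[0], regs[1])
    reg_a, reg_b = regions
    tables = {reg_a: table_a, reg_b: table_b}
    ordered = {r: _ordered_samples(design, r) for r in regions}
    if len(ordered[reg_a]) != len(ordered[reg_b]):
        raise ValueError("regions cover different (time, replicate) grids")

    matrices: dict[str, dict[str, DistanceMatrix]] = {m: {} for m in METRICS}
    for region in regions:
        tbl = tables[region].select_samples(ordered[region])
        for metric in METRICS:
            matrices[metric][region] = distance_matrix(tbl, metric, tree=tree)

    # Mantel per metric, rows matched on (time_point, replicate)
    mantel_results: dict[str, MantelResult] = {}
    for metric in METRICS:
        Da = matrices[metric][reg_a]
        Db = matrices[metric][reg_b]
        Db_matched = DistanceMatrix(Da.sample_ids, Db.values, Db.metric)
        mantel_results[metric] = mantel(Da, Db_matched, n_perm=n_perm, seed=seed)

    # NMDS on Bray-Curtis per region, then Procrustes
    ord_a = nmds(matrices["bray_curtis"][reg_a], n_starts=nmds_starts, seed=seed)
    ord_b = nmds(matrices["bray_curtis"][reg_b], n_starts=nmds_starts, seed=seed)
    proc = procrustes(ord_a.configuration, ord_b.configuration, n_perm=n_perm, seed=seed)

    mw: dict[str, dict[str, MovingWindowSeries]] = {}
    mw_r: dict[str, float] = {}
    decay: dict[str, dict[str, list[DecayFit]]] = {}
    slope_tests: dict[str, TwoSampleTestResult] = {}
    for metric in METRICS:
        mw[metric] = {
            region: moving_window(matrices[metric][region], design, region)
            for region in regions
        }
        r, _ = stats.pearsonr(mw[metric][reg_a].means, mw[metric][reg_b].means)
        mw_r[metric] = float(r)
        decay[metric] = {
            region: similarity_decay(matrices[metric][region], design, region)
            for region in regions
        }
        slope_tests[metric] = compare_slopes(
            [f.slope for f in decay[metric][reg_a]],
            [f.slope for f in decay[metric][reg_b]],
        )

    str_fits = {
        region: taxa_time_relationship(tables[region], design, region)
        for region in regions
    }
    w_test = compare_slopes(
        [f.w for f in str_fits[reg_a]], [f.w for f in str_fits[reg_b]]
    )

    cores = {
        region: detect_core(tables[region], design, region) for region in regions
    }
    shared_shares = None
    if taxonomy is not None:
        shared = shared_core(
            cores[reg_a], cores[reg_b], taxonomy, table_a, table_b, design
        )
        shared_shares = shared_core_summary(shared)

    return RegionComparisonReport(
        regions=regions,
        mantel=mantel_results,
        procrustes=proc,
        nmds_stress={reg_a: ord_a.stress, reg_b: ord_b.stress},
        moving_window_r=mw_r,
        moving_window=mw,
        decay_fits=decay,
        slope_tests=slope_tests,
        str_fits=str_fits,
        w_test=w_test,
        cores=cores,
        shared_core_shares=shared_shares,
    )
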