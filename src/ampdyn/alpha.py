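"""Alpha diversity: subsampling normalization, rarefaction, Shannon,
observed richness, and the between-region comparison.

Sequencing depth varies between samples, so richness and Shannon are computed
on subsamples drawn without replacement at a common depth (2125 reads by
default, configurable).  Subsampling without replacement is a multivariate
hypergeometric draw, which gives a closed-form expected richness used as the
oracle for the Monte-Carlo rarefaction curves.

Shannon entropy uses the natural log (mothur convention), so
0 <= H <= ln(S_obs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import CommunityTable, TimeSeriesDesign

DEFAULT_DEPTH = 2125
DEFAULT_ITERATIONS = 1000


@dataclass
class AlphaRecord:
    sample_id: str
    depth: int
    observed_otus: int
    shannon: float


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    mean_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    iterations: int


@dataclass
class PairedTestResult:
    difference: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def rarefy(counts: np.ndarray, depth: int, seed: int | np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    A single multivariate hypergeometric draw: each read in the pool is
    equally likely to be kept, so per-taxon output means are depth*N_i/N.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def expected_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form mean number of taxa observed in a subsample of ``depth``:

        E[S] = sum_i 1 - C(N - N_i, depth) / C(N, depth)

    evaluated with log-gamma for stability.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if depth > N:
        raise ValueError(f"depth {depth} exceeds total count {N}")
    if depth == 0:
        return 0.0

    def log_choose(n: np.ndarray, k: int) -> np.ndarray:
        return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)

    rest = N - counts  # pool size without taxon i
    p_absent = np.zeros(len(counts))
    feasible = rest >= depth  # else the subsample must contain taxon i
    p_absent[feasible] = np.exp(log_choose(rest[feasible], depth) - log_choose(N, depth))
    return float(np.sum(1.0 - p_absent))


def observed_richness(counts: np.ndarray) -> int:
    return int(np.count_nonzero(np.asarray(counts)))


def shannon(counts: np.ndarray) -> float:
    """H = -sum p_i ln p_i over taxa with nonzero counts (natural log)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefaction_curve(
    counts: np.ndarray,
    depths: np.ndarray,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
) -> RarefactionCurve:
    """Monte-Carlo rarefaction: per depth, mean observed richness and the
    empirical 2.5/97.5-percentile interval over ``iterations`` independent
    subsamples."""
    counts = np.asarray(counts, dtype=np.int64)
    depths = np.asarray(sorted(int(d) for d in depths))
    if depths.max() > counts.sum():
        raise ValueError(f"max depth {depths.max()} exceeds total count {counts.sum()}")
    rng = np.random.default_rng(seed)
    means, lows, highs = [], [], []
    for depth in depths:
        richness = np.array(
            [
                observed_richness(rng.multivariate_hypergeometric(counts, depth))
                for _ in range(iterations)
            ]
        )
        means.append(richness.mean())
        lows.append(np.percentile(richness, 2.5))
        highs.append(np.percentile(richness, 97.5))
    return RarefactionCurve(
        depths, np.array(means), np.array(lows), np.array(highs), iterations
    )


def alpha_record(
    sample_id: str,
    counts: np.ndarray,
    depth: int | None = DEFAULT_DEPTH,
    seed: int | np.random.Generator = 0,
) -> AlphaRecord:
    """Observed OTUs and Shannon for one sample, after optional rarefying."""
    counts = np.asarray(counts, dtype=np.int64)
    if depth is not None:
        counts = rarefy(counts, depth, seed)
        used = depth
    else:
        used = int(counts.sum())
    return AlphaRecord(sample_id, used, observed_richness(counts), shannon(counts))


def alpha_table(
    table: CommunityTable,
    depth: int | None = DEFAULT_DEPTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample AlphaRecords as a DataFrame; one child seed per sample so
    the subsamples are independent but reproducible."""
    rng = np.random.default_rng(seed)
    records = []
    for j, sample in enumerate(table.sample_ids):
        rec = alpha_record(sample, table.counts[:, j], depth, rng)
        records.append(
            {
                "sample_id": rec.sample_id,
                "depth": rec.depth,
                "observed_otus": rec.observed_otus,
                "shannon": rec.shannon,
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def replicate_averaged(
    alpha: pd.DataFrame, design: TimeSeriesDesign, region: str, column: str
) -> pd.Series:
    """Average an alpha-diversity column over technical replicates, returning
    one value per time point for the given region."""
    sub = design.frame[design.frame["region"] == region]
    values = alpha.loc[sub.index, column]
    return values.groupby(sub["time_point"]).mean().sort_index()


def compare_alpha(values_a: np.ndarray, values_b: np.ndarray) -> PairedTestResult:
    """Paired two-tailed t-test across time points.

    Both series must be aligned on the same time points with replicates
    already averaged; time is the blocking factor.  A zero-variance
    difference is degenerate: p = 1 for identical series, p = 0 (flagged)
    for an exact constant shift.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned on the same time points")
    n = len(a)
    if n < 3:
        raise ValueError("need >= 3 paired time points")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, df, 1.0, degenerate=True)
        return PairedTestResult(mean, np.inf if mean > 0 else -np.inf, df, 0.0, True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(mean, float(t), df, float(p))
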