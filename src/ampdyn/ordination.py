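"""Ordination and permutation inference on distance matrices.

Implements principal coordinates analysis (PCoA), nonmetric multidimensional
scaling (NMDS, Kruskal stress-1 minimized by majorization with isotonic
regression), Procrustes superimposition with the PROTEST permutation test,
the Mantel test, and canonical analysis of principal coordinates (CAP,
i.e. distance-based RDA: PCoA axes regressed on constraints, with an
ANOVA-like permutation test on the pseudo-F).

All permutation p-values follow the convention (count of null >= observed
+ 1) / (n_perm + 1), so the observed statistic is a member of its own null.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .io_formats import DistanceMatrix

logger = logging.getLogger("ampdyn")


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    configuration: np.ndarray  # n x k coordinates
    method: str  # "pcoa" | "nmds"
    stress: float | None = None  # Kruskal stress-1, NMDS only
    eigenvalues: np.ndarray | None = None  # PCoA only, decreasing
    converged: bool = True
    stress_trace: list[float] = field(default_factory=list)


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p: float | None
    permutations: int


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int


@dataclass
class CAPResult:
    eigenvalues: np.ndarray  # constrained axis eigenvalues, decreasing
    proportion_constrained: float
    pseudo_f: float
    p: float | None
    constraint_names: list[str]
    permutations: int
    rank: int


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def _gower_center(values: np.ndarray) -> np.ndarray:
    a = -0.5 * values**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(D: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Gower double-centering of -D^2/2, eigendecomposition; coordinates are
    eigenvectors scaled by sqrt of the positive eigenvalues.  Negative
    eigenvalues (non-Euclidean input) are reported but carry no axis."""
    n = D.n
    explicit_k = k is not None
    if k is None:
        k = n - 1
    if k >= n:
        raise ValueError(f"k must be < n = {n}")
    eigval, eigvec = np.linalg.eigh(_gower_center(D.values))
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    n_pos = int(np.sum(eigval > tol))
    if k > n_pos:
        if explicit_k:
            logger.warning("requested %d axes but only %d positive eigenvalues", k, n_pos)
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))
    return OrdinationResult(list(D.sample_ids), coords, "pcoa", eigenvalues=eigval)


def pcoa_axes(D: DistanceMatrix) -> tuple[np.ndarray, float]:
    """All positive-eigenvalue PCoA axes and the total (positive) inertia.
    The working representation behind CAP."""
    res = pcoa(D)
    eigval = res.eigenvalues
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval[eigval > tol]
    if (eigval < -tol).any():
        logger.info(
            "dropping %d negative eigenvalues (%.3g of total magnitude)",
            int((eigval < -tol).sum()),
            float(-eigval[eigval < -tol].sum() / max(pos.sum(), 1e-300)),
        )
    return res.configuration, float(pos.sum())


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """NMDS by SMACOF majorization with isotonic (pool-adjacent-violators)
    disparities; best of ``n_starts`` starts (the first seeded from PCoA,
    the rest random).  Only the rank order of D enters, so the solution is
    invariant under strictly monotone transforms of the input values.
    """
    n = D.n
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for k={k}")
    dissim = squareform(D.values, checks=False)
    order = np.argsort(dissim, kind="stable")
    rng = np.random.default_rng(seed)

    best: OrdinationResult | None = None
    for start in range(max(1, n_starts)):
        if start == 0:
            X = pcoa(D, k=min(k, n - 1)).configuration
            if X.shape[1] < k:  # degenerate input: pad with jitter
                X = np.hstack([X, 1e-3 * rng.standard_normal((n, k - X.shape[1]))])
        else:
            X = rng.standard_normal((n, k))
        trace: list[float] = []
        converged = False
        d = pdist(X)
        for _ in range(max_iter):
            # isotonic regression of configuration distances on D's ranks
            dhat = np.empty_like(d)
            dhat[order] = isotonic_regression(d[order])
            norm = float((dhat**2).sum())
            if norm > 0:
                dhat = dhat * math.sqrt(float((d**2).sum()) / norm)
            stress = _stress1(d, dhat)
            if trace and stress > trace[-1] + 1e-15:
                break  # majorization can no longer improve; keep previous X
            trace.append(stress)
            if len(trace) > 1 and trace[-2] - trace[-1] < tol:
                converged = True
                break
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio, checks=False)
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = B @ X / n
            d_new = pdist(X_new)
            X, d = X_new, d_new
        final = trace[-1] if trace else _stress1(d, d)
        if best is None or final < (best.stress or np.inf):
            best = OrdinationResult(
                list(D.sample_ids),
                X,
                "nmds",
                stress=final,
                converged=converged,
                stress_trace=trace,
            )
    assert best is not None
    # rotate to principal axes so axis 1 carries the dominant spread
    X = best.configuration - best.configuration.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    best.configuration = X @ vt.T
    if not best.converged:
        logger.warning("NMDS did not converge in %d iterations; best stress %.4g",
                       max_iter, best.stress)
    return best


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------


def _standardize(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    norm = np.sqrt((M**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration: zero spread")
    return M / norm


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares after optimal translation, rotation and
    scaling, with both configurations scaled to unit sum of squares:
    m2 = 1 - (sum of singular values of X'Y)^2."""
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    return max(0.0, 1.0 - float(s.sum()) ** 2)


def _pad_columns(M: np.ndarray, k: int) -> np.ndarray:
    if M.shape[1] < k:
        return np.hstack([M, np.zeros((M.shape[0], k - M.shape[1]))])
    return M


def procrustes(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesResult:
    """Procrustes superimposition of two configurations with aligned rows,
    plus the PROTEST permutation test (rows of Y permuted; one-sided on
    small m2).  correlation = sqrt(1 - m2)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    k = max(X.shape[1], Y.shape[1])
    Xs = _standardize(_pad_columns(X, k))
    Ys = _standardize(_pad_columns(Y, k))
    m2 = _procrustes_m2(Xs, Ys)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(Ys))
            if _procrustes_m2(Xs, _standardize(Ys[perm])) <= m2 + 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return ProcrustesResult(m2, math.sqrt(max(0.0, 1.0 - m2)), p, n_perm)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = math.sqrt(float((u**2).sum() * (v**2).sum()))
    if denom == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    return float((u * v).sum() / denom)


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same
    samples: Pearson r of the off-diagonal pairs, one-sided permutation p
    (sample relabelings of D2).  ``exact=True`` enumerates all n!
    relabelings instead of sampling them."""
    if D1.sample_ids != D2.sample_ids:
        if set(D1.sample_ids) != set(D2.sample_ids):
            raise ValueError("distance matrices cover different samples")
        D2 = D2.reorder(D1.sample_ids)
    n = D1.n
    iu = np.triu_indices(n, k=1)
    v1 = D1.values[iu]
    r_obs = _pearson(v1, D2.values[iu])
    if exact:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            permuted = D2.values[np.ix_(perm, perm)]
            if _pearson(v1, permuted[iu]) >= r_obs - 1e-15:
                count += 1
            total += 1
        return MantelResult(r_obs, count / total, total)
    if n_perm <= 0:
        return MantelResult(r_obs, float("nan"), 0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = D2.values[np.ix_(perm, perm)]
        if _pearson(v1, permuted[iu]) >= r_obs - 1e-15:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm)


# ---------------------------------------------------------------------------
# CAP (distance-based RDA)
# ---------------------------------------------------------------------------


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that add no rank (collinear or constant)."""
    kept_idx: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-10) > len(kept_idx):
            kept_idx.append(j)
        else:
            logger.warning("dropping collinear/constant constraint %r", names[j])
    return X[:, kept_idx], [names[j] for j in kept_idx]


def cap(
    D: DistanceMatrix,
    constraints: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> CAPResult:
    """Canonical analysis of principal coordinates.

    The distance matrix is embedded by PCoA (positive eigenvalues only,
    negatives dropped and logged); the axes are regressed on the centered
    (and by default unit-variance) constraints; the constrained inertia is
    the sum of squares of the fitted values.  Significance comes from an
    ANOVA-like permutation test on

        pseudo-F = (constrained / q) / (residual / (n - q - 1))

    with constraint rows permuted.  Samples with missing covariates must be
    dropped by the caller; q is the rank of the constraint matrix.
    """
    if isinstance(constraints, pd.DataFrame):
        names = [str(c) for c in constraints.columns]
        X = constraints.to_numpy(dtype=float)
    else:
        X = np.asarray(constraints, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != D.n:
        raise ValueError("constraint rows must align with the distance matrix samples")
    if np.isnan(X).any():
        raise ValueError("constraints contain missing values; drop those samples first")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        nonconst = sd > 0
        X = np.where(nonconst, X / np.where(nonconst, sd, 1.0), X)
    X, names = _drop_collinear(X, names)
    q = X.shape[1]
    if q == 0:
        raise ValueError("no usable constraints (all constant or collinear)")
    Y, total_inertia = pcoa_axes(D)
    n = D.n
    if n - q - 1 <= 0:
        raise ValueError(f"too few samples (n={n}) for q={q} constraints")

    def fit_stat(Xc: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        fitted = Xc @ beta
        constrained = float((fitted**2).sum())
        return constrained, fitted

    constrained, fitted = fit_stat(X)
    residual = max(total_inertia - constrained, 0.0)
    if constrained <= total_inertia * 1e-12:
        raise ValueError("zero constrained inertia: test undefined")
    if residual <= 0:
        raise ValueError("zero residual inertia: pseudo-F undefined")
    f_obs = (constrained / q) / (residual / (n - q - 1))
    sv = np.linalg.svd(fitted, compute_uv=False)
    eigenvalues = (sv**2)[sv**2 > sv.max() ** 2 * 1e-12] if sv.size else np.array([])

    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            c_perm, _ = fit_stat(X[rng.permutation(n)])
            r_perm = max(total_inertia - c_perm, 1e-300)
            if (c_perm / q) / (r_perm / (n - q - 1)) >= f_obs - 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return CAPResult(
        eigenvalues=np.sort(eigenvalues)[::-1],
        proportion_constrained=constrained / total_inertia,
        pseudo_f=float(f_obs),
        p=p,
        constraint_names=names,
        permutations=n_perm,
        rank=q,
    )
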