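"""Statistics for binary community fingerprints.

Gel fingerprints (16S DGGE for bacteria, PFGE genome-size bands for
viruses) reduce to binary presence/absence matrices of samples x bands.
This module carries those matrices through the ordination pipeline used to
test host-virus coupling in enrichment mesocosms:

* Jaccard dissimilarities between samples,
* nonmetric multidimensional scaling (Kruskal stress-1, SMACOF majorization
  alternated with monotone regression on dissimilarity ranks),
* Procrustes superposition of two ordinations with a permutation test
  (protest), repeated over an ensemble of independently restarted NMDS
  fits,
* PERMANOVA (distance-based pseudo-F) for treatment effects,
* Pearson correlation and the virus-to-prokaryote ratio (VPR).

Permutation p-values use the (count + 1)/(n_perm + 1) convention
throughout, so a p-value is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "BandMatrix",
    "OrdinationResult",
    "ProcrustesFit",
    "ProtestResult",
    "EnsembleCouplingResult",
    "PermanovaResult",
    "jaccard_distances",
    "nmds",
    "procrustes",
    "protest",
    "nmds_procrustes_ensemble",
    "permanova",
    "pearson_test",
    "vpr",
]

#: metadata columns a BandMatrix carries (with defaults for absent ones)
METADATA_COLUMNS = {
    "day": 0,
    "glucose_x": 0.0,
    "silicate": False,
    "nitrogen_source": "NH4",
}


@dataclass
class BandMatrix:
    """Binary samples x bands matrix with per-sample metadata.

    ``values``: DataFrame of 0/1 ints, index = sample ids, columns = band
    ids.  ``metadata``: DataFrame indexed like ``values`` with columns
    day, glucose_x, silicate, nitrogen_source.  Every sample must carry at
    least one band (all-zero rows make Jaccard undefined).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = None

    def __post_init__(self):
        vals = self.values
        if vals.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if vals.columns.has_duplicates:
            raise ValueError("duplicate band ids")
        arr = vals.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"non-binary value {arr[tuple(bad)]!r} at sample "
                f"{vals.index[bad[0]]!r}, band {vals.columns[bad[1]]!r}")
        empty = vals.index[arr.sum(axis=1) == 0]
        if len(empty):
            raise ValueError(f"samples with no bands present: {list(empty)}")
        self.values = vals.astype(np.int8)
        self.values.index.name = "sample_id"
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=vals.index)
        meta = self.metadata.reindex(vals.index)
        for col, default in METADATA_COLUMNS.items():
            if col not in meta.columns:
                meta[col] = default
        self.metadata = meta[list(METADATA_COLUMNS)]
        self.metadata.index.name = "sample_id"

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def band_ids(self) -> list:
        return list(self.values.columns)


def jaccard_distances(matrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarities, 1 - |intersection|/|union|.

    Accepts a :class:`BandMatrix` or a binary DataFrame/array.  Raises on
    all-zero rows, for which the coefficient is undefined.
    """
    if isinstance(matrix, BandMatrix):
        values, ids = matrix.values.to_numpy(), matrix.sample_ids
    elif isinstance(matrix, pd.DataFrame):
        values, ids = matrix.to_numpy(), list(matrix.index)
    else:
        values = np.asarray(matrix)
        ids = [str(i) for i in range(values.shape[0])]
    if not np.isin(values, (0, 1)).all():
        raise ValueError("band matrix must be binary")
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("Jaccard distance undefined for all-zero samples")
    condensed = pdist(values.astype(bool), metric="jaccard")
    return DistanceMatrix(squareform(condensed), ids=ids)


# ---------------------------------------------------------------------------
# nonmetric multidimensional scaling


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS solution: configuration, Kruskal stress-1 and convergence flag."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    seed: int | None

    @property
    def ids(self) -> list:
        return list(self.coordinates.index)

    def array(self) -> np.ndarray:
        return self.coordinates.to_numpy()


def _as_distance_array(distances):
    if isinstance(distances, DistanceMatrix):
        return distances.data, list(distances.ids)
    arr = np.asarray(distances, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distances must be a square matrix")
    if not np.allclose(arr, arr.T) or np.any(np.diag(arr) != 0):
        raise ValueError("distances must be symmetric with zero diagonal")
    return arr, [str(i) for i in range(arr.shape[0])]


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _monotone_disparities(delta: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Isotonic fit of configuration distances against dissimilarity ranks.

    Primary tie handling: within blocks of tied dissimilarities the fit is
    unconstrained, achieved by ordering tied pairs by their current
    configuration distance before pool-adjacent-violators.
    """
    order = np.lexsort((d, delta))
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    return dhat


def _classical_scaling(dist: np.ndarray, k: int) -> np.ndarray:
    """Torgerson principal-coordinates start for SMACOF."""
    n = dist.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (dist ** 2) @ J
    evals, evecs = np.linalg.eigh(G)
    idx = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)


def _smacof_run(dist: np.ndarray, X0: np.ndarray, max_iter: int,
                tol: float) -> tuple[np.ndarray, float, bool]:
    iu = np.triu_indices(dist.shape[0], k=1)
    delta = dist[iu]
    n = dist.shape[0]
    X = X0 - X0.mean(axis=0)
    d = pdist(X)
    if np.all(d == 0):
        X = X + 1e-6 * np.arange(X.size).reshape(X.shape)
        d = pdist(X)
    dhat = _monotone_disparities(delta, d)
    stress = _stress1(d, dhat)
    converged = False
    for _ in range(max_iter):
        # Guttman transform with the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        Bmat = np.zeros((n, n))
        Bmat[iu] = -ratio
        Bmat += Bmat.T
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X_new = Bmat @ X / n
        d_new = pdist(X_new)
        if np.all(d_new == 0):
            break
        dhat_new = _monotone_disparities(delta, d_new)
        stress_new = _stress1(d_new, dhat_new)
        if stress_new > stress:  # keep stress-1 monotone within a run
            break
        X, d, dhat = X_new, d_new, dhat_new
        if stress - stress_new < tol:
            stress = stress_new
            converged = True
            break
        stress = stress_new
    return X - X.mean(axis=0), stress, converged


def nmds(distances, k: int = 2, n_restarts: int = 20, max_iter: int = 500,
         tol: float = 1e-7, seed: int | None = None) -> OrdinationResult:
    """Kruskal nonmetric MDS of a distance matrix.

    Minimizes stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) over k-dimensional
    configurations, where dhat is the monotone regression of the
    configuration distances on the dissimilarity ranks.  Each restart
    alternates a Guttman (SMACOF) update with the monotone fit; restart 0
    starts from classical scaling, the rest from random Gaussian
    configurations.  The best-stress configuration is returned, centered
    and rotated to its principal axes.  Deterministic given ``seed``.
    """
    dist, ids = _as_distance_array(distances)
    n = dist.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k must be < number of samples ({n})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)

    best = None
    for restart in range(n_restarts):
        if restart == 0:
            X0 = _classical_scaling(dist, k)
            if np.allclose(X0, 0):
                X0 = rng.standard_normal((n, k))
        else:
            X0 = rng.standard_normal((n, k))
        X, stress, converged = _smacof_run(dist, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, converged)

    X, stress, converged = best
    # rotate to principal axes for a reproducible orientation
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    coords = pd.DataFrame(X, index=ids,
                          columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult(coords, stress, converged, seed)


# ---------------------------------------------------------------------------
# Procrustes superposition and protest


@dataclass(frozen=True)
class ProcrustesFit:
    """Symmetric Procrustes residual m2 and correlation sqrt(1 - m2)."""

    m2: float
    correlation: float


def _center_unit(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    norm = np.linalg.norm(Xc)
    if norm == 0:
        raise ValueError("degenerate configuration (all points coincide)")
    return Xc / norm


def _coerce_config(X) -> np.ndarray:
    if isinstance(X, OrdinationResult):
        X = X.array()
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("configuration must be a 2-D array")
    return X


def procrustes(X, Y) -> ProcrustesFit:
    """Symmetric Procrustes superposition of configuration Y onto X.

    Both configurations are centered and scaled to unit sum of squares;
    Y is then optimally rotated/reflected and rescaled onto X.  The
    residual sum of squares m2 = 1 - (sum of singular values of X'Y)^2
    lies in [0, 1]; the Procrustes correlation is sqrt(1 - m2).
    """
    X, Y = _coerce_config(X), _coerce_config(Y)
    if X.shape != Y.shape:
        raise ValueError(f"configuration shapes differ: {X.shape} vs {Y.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    s = np.linalg.svd(_center_unit(X).T @ _center_unit(Y), compute_uv=False)
    m2 = float(np.clip(1.0 - s.sum() ** 2, 0.0, 1.0))
    return ProcrustesFit(m2=m2, correlation=float(np.sqrt(1.0 - m2)))


@dataclass(frozen=True)
class ProtestResult:
    """Procrustes permutation test."""

    correlation: float
    m2: float
    p: float
    n_perm: int


def protest(X, Y, n_perm: int = 999, seed: int | None = None) -> ProtestResult:
    """Permutation test of Procrustes concordance between two configurations.

    Re-fits the superposition after randomly permuting the row order of Y;
    p = (1 + #{permuted correlation >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, Y = _coerce_config(X), _coerce_config(Y)
    fit = procrustes(X, Y)
    Xu, Yu = _center_unit(X), _center_unit(Y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = np.linalg.svd(Xu.T @ Yu[perm], compute_uv=False)
        corr = np.sqrt(np.clip(s.sum() ** 2, 0.0, 1.0))
        if corr >= fit.correlation - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ProtestResult(correlation=fit.correlation, m2=fit.m2,
                         p=p, n_perm=n_perm)


@dataclass(frozen=True)
class EnsembleCouplingResult:
    """Summary of repeated NMDS + protest couplings.

    ``median_p``/``pct_significant`` summarize the protest p-values over
    the repetitions; ``median_correlation`` the Procrustes correlations.
    """

    median_p: float
    pct_significant: float
    median_correlation: float
    n_repeats: int
    p_values: np.ndarray = field(repr=False, default=None)
    correlations: np.ndarray = field(repr=False, default=None)


def nmds_procrustes_ensemble(host, virus, n_repeats: int = 1000,
                             n_perm: int = 999, k: int = 2,
                             seed: int | None = None,
                             n_restarts: int = 4,
                             alpha: float = 0.05,
                             permutations_only: bool = False
                             ) -> EnsembleCouplingResult:
    """Couple two fingerprint matrices through an NMDS/protest ensemble.

    Each repetition re-runs the stochastic NMDS of both Jaccard matrices
    from fresh random starts and applies a protest to the resulting
    configurations; the distribution of p-values and Procrustes
    correlations over ``n_repeats`` repetitions is summarized by its
    median p, the percentage of repetitions significant at ``alpha``, and
    the median correlation.  With ``permutations_only=True`` the NMDS of
    each matrix is fit once and only the protest permutations are
    repeated (the alternative reading of "repeated permutations").
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    host_ids = host.sample_ids if isinstance(host, BandMatrix) else None
    virus_ids = virus.sample_ids if isinstance(virus, BandMatrix) else None
    if host_ids is not None and virus_ids is not None and host_ids != virus_ids:
        raise ValueError("host and virus matrices must share sample ids in order")
    d_host = jaccard_distances(host)
    d_virus = jaccard_distances(virus)

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_repeats if not permutations_only else n_repeats + 1)

    if permutations_only:
        base = int(children[-1].generate_state(1)[0] >> 1)
        ord_h = nmds(d_host, k=k, n_restarts=max(n_restarts, 20), seed=base)
        ord_v = nmds(d_virus, k=k, n_restarts=max(n_restarts, 20), seed=base + 1)

    p_values = np.empty(n_repeats)
    correlations = np.empty(n_repeats)
    for i, child in enumerate(children[:n_repeats]):
        s1, s3 = (int(s.generate_state(1)[0] >> 1) for s in child.spawn(2))
        if not permutations_only:
            # one fresh seed per repetition, shared by the two fits: two
            # identical matrices then yield identical configurations
            ord_h = nmds(d_host, k=k, n_restarts=n_restarts, seed=s1)
            ord_v = nmds(d_virus, k=k, n_restarts=n_restarts, seed=s1)
        res = protest(ord_h, ord_v, n_perm=n_perm, seed=s3)
        p_values[i] = res.p
        correlations[i] = res.correlation

    return EnsembleCouplingResult(
        median_p=float(np.median(p_values)),
        pct_significant=float(100.0 * np.mean(p_values < alpha)),
        median_correlation=float(np.median(correlations)),
        n_repeats=n_repeats,
        p_values=p_values,
        correlations=correlations,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based permutational ANOVA for one grouping factor."""

    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    df_between: int
    df_residual: int


def permanova(distances, grouping, n_perm: int = 99999,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Partitions the total sum of squares of the Gower-centered squared
    distance matrix into between- and within-group parts;
    pseudo-F = (SS_between/df_between)/(SS_within/df_residual), with a
    permutation p-value over random label assignments ((count+1)/(n+1)
    convention) and R2 = SS_between/SS_total.
    """
    dist, ids = _as_distance_array(distances)
    n = dist.shape[0]
    groups = np.asarray(grouping)
    if groups.shape != (n,):
        raise ValueError("grouping must have one label per sample")
    codes, counts = np.unique(groups, return_counts=True)
    a = len(codes)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if a >= n:
        raise ValueError("PERMANOVA needs residual degrees of freedom")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (dist ** 2) @ J
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValueError("total sum of squares is zero (all distances equal 0)")

    members = [np.flatnonzero(groups == c) for c in codes]

    def ss_between(index_sets):
        return sum(G[np.ix_(g, g)].sum() / len(g) for g in index_sets)

    df_between, df_residual = a - 1, n - a

    def pseudo_F(ssb):
        ssw = ss_total - ssb
        if ssw <= 1e-12 * ss_total:  # pure between-group structure
            return np.inf
        return (ssb / df_between) / (ssw / df_residual)

    ssb = ss_between(members)
    F_obs = pseudo_F(ssb)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_F(ss_between([perm[g] for g in members])) >= F_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermanovaResult(pseudo_F=float(F_obs), R2=float(ssb / ss_total),
                           p=p, n_permutations=n_perm,
                           df_between=df_between, df_residual=df_residual)


# ---------------------------------------------------------------------------
# simple bivariate statistics


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value.

    ``t = rho*sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.  Raises
    for n < 3 or constant series, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant series")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def vpr(virus_counts, prokaryote_counts) -> np.ndarray:
    """Virus-to-prokaryote ratio, elementwise.

    Small-virus counts over total prokaryote counts (both mL^-1).
    Dimensionless; invariant under common rescaling of both series.
    """
    v = np.asarray(virus_counts, dtype=float)
    b = np.asarray(prokaryote_counts, dtype=float)
    if v.shape != b.shape:
        raise ValueError("series must have equal length")
    if np.any(v < 0):
        raise ValueError("virus counts must be non-negative")
    bad = np.flatnonzero(b <= 0)
    if len(bad):
        raise ValueError(
            f"prokaryote count must be positive (violated at index {bad[0]})")
    return v / b
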