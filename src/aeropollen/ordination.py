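"""Bray–Curtis dissimilarity, non-metric MDS, and environmental vector fitting.

Cities are compared on their pollen composition with the Bray–Curtis
coefficient, d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), the standard
abundance dissimilarity in community ecology.  By default percentages are
square-root transformed first, the conventional down-weighting of dominant
taxa before a Bray–Curtis ordination; the raw and Wisconsin-standardised
variants are available.

The 2-D configuration is found by Kruskal-style non-metric MDS: the
configuration distances need only be *monotone* in the input
dissimilarities, and the residual of the monotone (isotonic) fit is the
stress.  Optimisation is SMACOF with the Guttman transform, run from one
classical-scaling start plus many random restarts, keeping the lowest
stress.  Stress-1 below ~0.2 is conventionally read as a good 2-D picture.

Environmental vectors: each site covariate is regressed on the ordination
coordinates; the fitted direction is the gradient of the covariate across
the map, r^2 its squared multiple correlation, and significance comes from
permuting site labels (one-sided on r^2, with the +1 correction so p is
never zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, ValidationError

__all__ = [
    "select_top_taxa",
    "bray_curtis",
    "dissimilarity_matrix",
    "nmds",
    "OrdinationResult",
    "fit_env_vectors",
    "EnvFitResult",
]

logger = logging.getLogger(__name__)


def select_top_taxa(matrix: pd.DataFrame, k: int = 8) -> pd.DataFrame:
    """Keep the union over sites of each site's k highest-percentage taxa.

    Column order of the original matrix is preserved; values are not
    renormalised — the retained cells keep their percentages of the full
    pollen sum.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    n_taxa = matrix.shape[1]
    if k >= n_taxa:
        if k > n_taxa:
            logger.warning("select_top_taxa: k=%d > %d taxa; keeping all", k, n_taxa)
        return matrix.copy()
    keep: set[str] = set()
    for _, row in matrix.iterrows():
        keep.update(row.dropna().nlargest(k).index)
    return matrix[[c for c in matrix.columns if c in keep]].copy()


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between site rows.

    Absent cells are treated as 0 abundance.  A site whose row is entirely
    zero makes the coefficient undefined and raises.
    """
    values = matrix.fillna(0.0).to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("negative abundances in composition matrix")
    zero = matrix.index[values.sum(axis=1) == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero site row(s): {zero}")
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def dissimilarity_matrix(
    matrix: pd.DataFrame,
    metric: str = "braycurtis",
    transform: str | None = "sqrt",
) -> pd.DataFrame:
    """Dissimilarities with an optional abundance pre-transform.

    ``transform``: None (raw values), ``"sqrt"`` (default; dampens dominant
    taxa) or ``"wisconsin"`` (double standardisation by species maxima and
    site totals).  ``metric``: ``braycurtis``, ``euclidean`` or ``jaccard``
    (on presence/absence).
    """
    values = matrix.fillna(0.0)
    if transform == "sqrt":
        values = np.sqrt(values)
    elif transform == "wisconsin":
        values = values / values.max(axis=0).replace(0, 1)
        values = values.div(values.sum(axis=1), axis=0)
    elif transform is not None and transform != "none":
        raise ConfigurationError(f"unknown transform {transform!r}")
    if metric == "jaccard":
        values = (values > 0).astype(float)
    elif metric not in ("braycurtis", "euclidean"):
        raise ConfigurationError(f"unknown metric {metric!r}")
    if metric == "braycurtis":
        return bray_curtis(values)
    d = squareform(pdist(values.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class OrdinationResult:
    """Best configuration found by :func:`nmds`."""

    coords: pd.DataFrame  # sites x axes, centred
    stress: float  # Kruskal stress-1
    n_restarts: int
    seed: int
    converged: bool
    stress_per_start: np.ndarray = field(repr=False, default=None)


def _stress_and_disparities(
    dist_flat: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and monotone disparities for one configuration.

    ``order`` sorts pairs by input dissimilarity (ties broken by current
    configuration distance — the primary tie approach, letting tied input
    values take different disparities).
    """
    fitted = isotonic_regression(dist_flat[order]).x
    disparities = np.empty_like(dist_flat)
    disparities[order] = fitted
    denom = float(dist_flat @ dist_flat)
    if denom == 0:
        return np.inf, disparities
    stress = np.sqrt(((dist_flat - disparities) ** 2).sum() / denom)
    return float(stress), disparities


def _guttman_update(X: np.ndarray, dist_flat: np.ndarray, disparities: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist_flat > 0, disparities / dist_flat, 0.0)
    B = -squareform(ratio)
    np.fill_diagonal(B, -B.sum(axis=1))
    return (B @ X) / n


def _nmds_single(
    d_flat: np.ndarray, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    X = init - init.mean(axis=0)
    converged = False
    dist_flat = pdist(X)
    order = np.lexsort((dist_flat, d_flat))
    stress, disparities = _stress_and_disparities(dist_flat, order)
    for _ in range(max_iter):
        X = _guttman_update(X, dist_flat, disparities)
        dist_flat = pdist(X)
        order = np.lexsort((dist_flat, d_flat))
        new_stress, disparities = _stress_and_disparities(dist_flat, order)
        if stress - new_stress < tol * max(stress, 1e-12):
            stress = min(stress, new_stress)
            converged = True
            break
        stress = new_stress
    return X - X.mean(axis=0), stress, converged


def classical_scaling(D: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Metric (Torgerson) scaling used as the deterministic nMDS start."""
    n = len(D)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    idx = np.argsort(eigval)[::-1][:n_dims]
    return eigvec[:, idx] * np.sqrt(np.clip(eigval[idx], 0.0, None))


def nmds(
    dissimilarity: pd.DataFrame,
    n_dims: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with monotone regression.

    Runs one classical-scaling initialisation plus ``n_restarts`` random
    Gaussian initialisations and returns the configuration with the lowest
    Kruskal stress-1.  Deterministic given ``seed``.
    """
    D = dissimilarity.to_numpy(dtype=float)
    n = len(D)
    if n < 3:
        raise ValidationError(f"nMDS needs >= 3 sites, got {n}")
    if n_dims >= n:
        raise ConfigurationError(f"n_dims={n_dims} must be < n_sites={n}")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValidationError("dissimilarity matrix must be symmetric with zero diagonal")
    d_flat = squareform(D, checks=False)
    rng = np.random.default_rng(seed)
    inits = [classical_scaling(D, n_dims)]
    inits += [rng.standard_normal((n, n_dims)) for _ in range(n_restarts)]
    best_X, best_stress, best_conv = None, np.inf, False
    stresses = np.empty(len(inits))
    for i, init in enumerate(inits):
        X, stress, conv = _nmds_single(d_flat, init, max_iter, tol)
        stresses[i] = stress
        if stress < best_stress:
            best_X, best_stress, best_conv = X, stress, conv
    coords = pd.DataFrame(
        best_X,
        index=dissimilarity.index,
        columns=[f"axis{i+1}" for i in range(n_dims)],
    )
    return OrdinationResult(
        coords=coords,
        stress=best_stress,
        n_restarts=n_restarts,
        seed=seed,
        converged=best_conv,
        stress_per_start=stresses,
    )


@dataclass
class EnvFitResult:
    """Fitted environmental vector for one covariate."""

    variable: str
    direction: np.ndarray  # unit vector in the ordination plane
    r2: float
    p_value: float
    n_permutations: int
    seed: int


def _projection_r2(coords_centred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    beta, *_ = np.linalg.lstsq(coords_centred, yc, rcond=None)
    resid = yc - coords_centred @ beta
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return r2, beta


def fit_env_vectors(
    ordination: OrdinationResult | pd.DataFrame,
    env: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each environmental covariate as a vector over the ordination.

    For covariate y: regress centred y on the centred coordinates; the
    direction is the unit coefficient vector, r^2 the squared multiple
    correlation (invariant under rotation/reflection of the axes), and the
    p-value the permutation tail probability
    ``(1 + #{permuted r^2 >= observed}) / (1 + n_permutations)``.

    ``env`` rows must align with the ordination sites (reindexed by site
    label).  Returns a DataFrame indexed by variable with columns ``axis1,
    axis2, ..., r2, p_value``.
    """
    coords = ordination.coords if isinstance(ordination, OrdinationResult) else ordination
    missing = set(coords.index) - set(env.index)
    if missing:
        raise ValidationError(f"environment table missing site(s): {sorted(missing)}")
    env = env.reindex(coords.index)
    Xc = coords.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = len(Xc)
    rows = []
    for var in env.columns:
        y = env[var].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValidationError(f"constant environmental variable {var!r}")
        r2, beta = _projection_r2(Xc, y)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        exceed = 0
        for _ in range(n_permutations):
            perm_r2, _ = _projection_r2(Xc, y[rng.permutation(n)])
            if perm_r2 >= r2:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        rows.append(
            {"variable": var}
            | {f"axis{i+1}": direction[i] for i in range(Xc.shape[1])}
            | {"r2": r2, "p_value": p}
        )
    return pd.DataFrame(rows).set_index("variable")
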