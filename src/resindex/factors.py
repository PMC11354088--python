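"""Factorability testing, correlation-matrix PCA, varimax and retention.

The chain here decides the structure of the composite index: KMO and
Bartlett's sphericity test gauge whether the indicator correlations are
strong enough for PCA; PCA of the sample correlation matrix yields
eigenvalues and loadings; Horn's parallel analysis (adjusted eigenvalues
> 1) fixes the number of retained components; varimax rotation of the
retained loadings gives simple structure; and each indicator is assigned to
the component on which it loads most strongly (absolute value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .registry import ValidationError

__all__ = [
    "FactorModelResult",
    "SubIndexAssignment",
    "SuitabilityReport",
    "assign_to_subindices",
    "bartlett_sphericity",
    "correlation_matrix",
    "fit_factor_model",
    "kmo_statistic",
    "parallel_analysis",
    "pca_correlation",
    "varimax",
]


@dataclass(frozen=True)
class SuitabilityReport:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def correlation_matrix(z: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("input contains non-finite values")
    return np.corrcoef(x, rowvar=False)


def _check_square_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have a unit diagonal")
    return R


def kmo_statistic(R: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum of squared off-diagonal correlations over that sum plus the
    sum of squared off-diagonal anti-image partial correlations, where the
    partials come from the scaled inverse of R.
    """
    R = _check_square_corr(R)
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "correlation matrix is singular; drop collinear indicators or add a ridge"
        ) from exc
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that R is an identity matrix.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det R, with p(p-1)/2 degrees of
    freedom.
    """
    R = _check_square_corr(R)
    p = R.shape[0]
    if n <= p:
        raise ValidationError("sample size must exceed the number of indicators")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValidationError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def suitability(z: pd.DataFrame | np.ndarray) -> SuitabilityReport:
    x = np.asarray(z, dtype=float)
    R = correlation_matrix(x)
    chi2, df, pval = bartlett_sphericity(R, n=x.shape[0])
    return SuitabilityReport(kmo=kmo_statistic(R), bartlett_chi2=chi2, bartlett_df=df, bartlett_p=pval)


@dataclass
class FactorModelResult:
    """Eigenstructure of the correlation matrix plus retention decision."""

    eigenvalues: np.ndarray  # descending, length p
    variance_explained: np.ndarray  # per-component proportion
    loadings_unrotated: pd.DataFrame  # p x p
    loadings_rotated: pd.DataFrame | None = None  # p x k
    rotation: np.ndarray | None = None  # k x k orthogonal
    k_retained: int | None = None
    random_eigenvalue_means: np.ndarray | None = None
    adjusted_eigenvalues: np.ndarray | None = None
    suitability: SuitabilityReport | None = None

    @property
    def n_vars(self) -> int:
        return self.loadings_unrotated.shape[0]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_correlation(z: pd.DataFrame | np.ndarray) -> FactorModelResult:
    """PCA via eigendecomposition of the sample correlation matrix.

    Unrotated loadings are eigenvectors scaled by the square root of their
    eigenvalues, ordered by descending eigenvalue, with a deterministic sign
    convention (largest-magnitude element of each eigenvector positive).
    """
    if isinstance(z, pd.DataFrame):
        columns = list(z.columns)
        x = z.to_numpy(dtype=float)
    else:
        x = np.asarray(z, dtype=float)
        columns = [f"v{j + 1}" for j in range(x.shape[1])]
    R = correlation_matrix(x)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = _fix_signs(eigvecs[:, order])
    eigvals = np.clip(eigvals, 0.0, None)
    p = R.shape[0]
    loadings = eigvecs * np.sqrt(eigvals)
    return FactorModelResult(
        eigenvalues=eigvals,
        variance_explained=eigvals / p,
        loadings_unrotated=pd.DataFrame(
            loadings, index=columns, columns=[f"PC{j + 1}" for j in range(p)]
        ),
    )


def _varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax objective: per-column variance of squared loadings."""
    p = L.shape[0]
    sq = L**2
    return float(np.sum(sq**2) / p - np.sum(np.sum(sq, axis=0) ** 2) / p**2)


def varimax(
    loadings: pd.DataFrame | np.ndarray,
    kaiser_normalize: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation by iterative pairwise plane rotations.

    Returns ``(rotated, T)`` with ``rotated = loadings @ T`` and T
    orthogonal. ``kaiser_normalize`` rescales rows to unit communality
    before rotating (off by default). k = 1 returns the input unchanged.
    """
    is_frame = isinstance(loadings, pd.DataFrame)
    L0 = loadings.to_numpy(dtype=float) if is_frame else np.asarray(loadings, dtype=float)
    if L0.ndim != 2 or L0.shape[1] < 1:
        raise ValidationError("loadings must be a p x k matrix with k >= 1")
    p, k = L0.shape
    T = np.eye(k)
    if k > 1:
        if kaiser_normalize:
            h = np.sqrt(np.sum(L0**2, axis=1))
            h[h == 0] = 1.0
            L = L0 / h[:, None]
        else:
            h = None
            L = L0.copy()
        crit = _varimax_criterion(L)
        for _ in range(max_iter):
            for a in range(k - 1):
                for b in range(a + 1, k):
                    x, y = L[:, a], L[:, b]
                    u = x**2 - y**2
                    v = 2.0 * x * y
                    A, B = u.sum(), v.sum()
                    C = np.sum(u**2 - v**2)
                    D = np.sum(2.0 * u * v)
                    num = D - 2.0 * A * B / p
                    den = C - (A**2 - B**2) / p
                    phi = 0.25 * np.arctan2(num, den)
                    if abs(phi) < 1e-12:
                        continue
                    c, s = np.cos(phi), np.sin(phi)
                    rot = np.array([[c, -s], [s, c]])
                    L[:, [a, b]] = L[:, [a, b]] @ rot
                    T[:, [a, b]] = T[:, [a, b]] @ rot
            new_crit = _varimax_criterion(L)
            if new_crit - crit < tol:
                break
            crit = new_crit
        if h is not None:
            L = L * h[:, None]
        rotated = L
    else:
        rotated = L0.copy()
    if is_frame:
        rotated = pd.DataFrame(
            rotated,
            index=loadings.index,
            columns=[f"PC{j + 1}" for j in range(k)],
        )
    return rotated, T


def parallel_analysis(
    z: pd.DataFrame | np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
    quantile: float | None = None,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Horn's parallel analysis on correlation-matrix eigenvalues.

    Simulates ``n_reps`` standard-normal datasets of the same n x p shape,
    records the eigenvalues of each simulated correlation matrix, and takes
    the per-rank mean (or the given ``quantile``) as the random reference.
    Adjusted eigenvalue_j = observed_j - (reference_j - 1); the retained
    count is the length of the leading run of adjusted eigenvalues > 1.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be at least 1")
    x = np.asarray(z, dtype=float)
    n, p = x.shape
    observed = pca_correlation(x).eigenvalues
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        sim = rng.standard_normal((n, p))
        ev = np.linalg.eigvalsh(np.corrcoef(sim, rowvar=False))
        sims[r] = ev[::-1]
    if quantile is None:
        reference = sims.mean(axis=0)
    else:
        reference = np.quantile(sims, quantile, axis=0)
    adjusted = observed - (reference - 1.0)
    k = 0
    for val in adjusted:
        if val > 1.0:
            k += 1
        else:
            break
    return k, reference, adjusted


@dataclass
class SubIndexAssignment:
    """Indicator -> retained component map from maximum absolute loading."""

    component_of: pd.Series  # indicator id -> component index (0-based)
    members: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_i(self) -> dict[int, int]:
        return {c: len(m) for c, m in self.members.items()}

    @property
    def n_components(self) -> int:
        return len(self.members)


def assign_to_subindices(loadings_rotated: pd.DataFrame) -> SubIndexAssignment:
    """Assign each indicator to the component with its largest |loading|.

    Ties break toward the lower component index. A component left without
    members triggers a warning (the sub-index would be empty).
    """
    if loadings_rotated.shape[1] < 1:
        raise ValidationError("need at least one retained component")
    abs_load = loadings_rotated.abs().to_numpy()
    comp = np.argmax(abs_load, axis=1)  # argmax takes first on ties
    component_of = pd.Series(comp, index=loadings_rotated.index, name="component")
    members: dict[int, list[str]] = {c: [] for c in range(loadings_rotated.shape[1])}
    for ind, c in component_of.items():
        members[int(c)].append(str(ind))
    empty = [c for c, m in members.items() if not m]
    if empty:
        warnings.warn(f"components with no assigned indicators: {empty}", stacklevel=2)
    return SubIndexAssignment(component_of=component_of, members=members)


def fit_factor_model(
    z: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    quantile: float | None = None,
    kaiser_normalize: bool = False,
    rotate_all: bool = False,
) -> FactorModelResult:
    """Run the full chain: suitability, PCA, retention, rotation.

    By default only the retained components are rotated; ``rotate_all``
    rotates all p components first and then keeps the leading k.
    """
    result = pca_correlation(z)
    result.suitability = suitability(z)
    k, reference, adjusted = parallel_analysis(z, n_reps=n_reps, seed=seed, quantile=quantile)
    result.k_retained = k
    result.random_eigenvalue_means = reference
    result.adjusted_eigenvalues = adjusted
    if k >= 1:
        base = result.loadings_unrotated if rotate_all else result.loadings_unrotated.iloc[:, :k]
        rotated, T = varimax(base, kaiser_normalize=kaiser_normalize)
        result.loadings_rotated = rotated.iloc[:, :k]
        result.rotation = T
    return result
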