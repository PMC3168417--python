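"""PCA compression and Mahalanobis distance in score space.

PCA is computed by singular value decomposition of the centered spectra
matrix (stable when channels greatly outnumber samples).  The Mahalanobis
distance of a query score vector u from a reference group with mean u_ref
and covariance S is

    d = sqrt( (u - u_ref)^T S^-1 (u - u_ref) )

with S the unbiased (n-1) covariance of the reference observations.  A
hard constraint applies: the number of score components must be strictly
smaller than the number of reference observations, otherwise S is rank
deficient and its inverse meaningless.  Near-singular S (condition number
above 1e12) is ridge-regularized as S + lambda*I with
lambda = 1e-8 * trace(S)/p, and the event is recorded on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CenteringModel
from .spectra import SpectraSet

__all__ = [
    "PCAModel",
    "ScoreMatrix",
    "ReferenceScores",
    "fit_pca",
    "select_n_components",
    "project",
    "build_reference",
    "mahalanobis_distance",
]

COND_THRESHOLD = 1e12
RIDGE_SCALE = 1e-8


@dataclass
class PCAModel:
    """Loadings and explained variance of a fitted PCA compression."""

    loadings: np.ndarray  # components x channels
    explained_variance: np.ndarray  # absolute, per component
    explained_variance_ratio: np.ndarray
    n_samples_fit: int
    centering: CenteringModel | None = None
    grid: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass
class ScoreMatrix:
    """Sample scores on the PCA components."""

    scores: np.ndarray  # samples x components
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[0] != len(self.sample_ids):
            raise ValueError("one score row per sample id required")

    def select(self, sample_ids: list[str]) -> "ScoreMatrix":
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"sample ids not in score matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ScoreMatrix(self.scores[idx], list(sample_ids))

    def truncate(self, n_components: int) -> "ScoreMatrix":
        return ScoreMatrix(self.scores[:, :n_components], list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"score_{j + 1}" for j in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class ReferenceScores:
    """Reference-group scores with their mean and unbiased covariance."""

    scores: np.ndarray  # observations x components
    mean: np.ndarray
    covariance: np.ndarray
    regularized: bool = field(default=False)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(sset: SpectraSet, centering: CenteringModel | None = None) -> tuple[PCAModel, ScoreMatrix]:
    """SVD-based PCA of an already mean-centered spectra set.

    Keeps min(n_samples - 1, n_channels) components; with all components
    retained, scores @ loadings reconstructs the input exactly (to fp).
    """
    X = sset.absorbance
    if sset.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("spectra matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = min(sset.n_samples - 1, sset.n_channels)
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    var = s**2 / max(sset.n_samples - 1, 1)
    total = float(np.sum(s**2))
    ratio = s**2 / total if total > 0 else np.zeros_like(s)
    model = PCAModel(
        loadings=Vt,
        explained_variance=var,
        explained_variance_ratio=ratio,
        n_samples_fit=sset.n_samples,
        centering=centering,
        grid=sset.grid.copy(),
    )
    scores = ScoreMatrix(U * s, sset.sample_ids)
    return model, scores


def select_n_components(model: PCAModel, target: float) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches target."""
    if not 0 < target <= 1:
        raise ValueError("target variance fraction must be in (0, 1]")
    cum = np.cumsum(model.explained_variance_ratio)
    k = int(np.searchsorted(cum, target - 1e-12)) + 1
    return min(k, model.n_components)


def project(model: PCAModel, sset: SpectraSet) -> ScoreMatrix:
    """Project spectra onto a fitted PCA basis.

    Spectra that have not been mean-centered yet (no "mean_center" step in
    their log) are centered with the model's stored training mean first.
    """
    if model.grid is not None:
        if sset.n_channels != model.grid.size or not np.allclose(sset.grid, model.grid):
            raise ValueError("wavenumber grid differs from the PCA fitting grid")
    X = sset.absorbance
    if not sset.has_step("mean_center"):
        if model.centering is None:
            raise ValueError("set is uncentered and the model stores no centering")
        X = X - model.centering.mean_spectrum
    return ScoreMatrix(X @ model.loadings.T, sset.sample_ids)


def build_reference(scores: ScoreMatrix, ref_ids: list[str], n_components: int) -> ReferenceScores:
    """Reference mean and covariance from the first ``n_components`` scores.

    Enforces the observation-count constraint: the number of score
    variables must be strictly less than the number of reference
    observations, or the covariance cannot be inverted.
    """
    if not ref_ids:
        raise ValueError("ref_ids must be nonempty")
    sub = scores.select(ref_ids)
    n_obs = sub.scores.shape[0]
    if n_components >= n_obs:
        raise ValueError(
            f"{n_components} score components with only {n_obs} reference "
            "observations: components must be strictly fewer than observations"
        )
    if n_components > scores.scores.shape[1]:
        raise ValueError("n_components exceeds available score columns")
    pts = sub.scores[:, :n_components]
    mean = pts.mean(axis=0)
    cov = np.atleast_2d(np.cov(pts, rowvar=False, ddof=1))
    return ReferenceScores(scores=pts, mean=mean, covariance=cov)


def ledoit_wolf_intensity(obs: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity toward the scaled identity.

    Estimated from the observations themselves; large when the sample
    covariance is dominated by estimation noise (few observations per
    dimension), near zero when it is well determined.
    """
    X = np.asarray(obs, float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n
    mu = np.trace(S) / p
    delta2 = float(np.sum((S - mu * np.eye(p)) ** 2)) / p
    if delta2 <= 0:
        return 0.0
    beta2 = 0.0
    for k in range(n):
        xk = Xc[k][:, None]
        beta2 += float(np.sum((xk @ xk.T - S) ** 2))
    beta2 /= n**2 * p
    return float(min(1.0, beta2 / delta2))


def _inverse_covariance(ref: ReferenceScores, shrinkage: float | str = 0.0) -> np.ndarray:
    S = ref.covariance
    p = S.shape[0]
    mu = np.trace(S) / p
    if shrinkage == "lw":
        shrinkage = ledoit_wolf_intensity(ref.scores)
    if shrinkage:
        S = (1.0 - shrinkage) * S + shrinkage * mu * np.eye(p)
        ref.regularized = True
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        lam = RIDGE_SCALE * mu
        if lam <= 0:
            lam = RIDGE_SCALE
        S = S + lam * np.eye(p)
        ref.regularized = True
    return np.linalg.inv(S)


def mahalanobis_distance(
    ref: ReferenceScores,
    query: ScoreMatrix | np.ndarray,
    shrinkage: float | str = 0.0,
) -> np.ndarray:
    """Mahalanobis distance d (square root scale) of each query from the reference.

    By default the covariance is inverted as-is (with the numerical ridge
    for near-singular matrices).  ``shrinkage`` blends the covariance
    toward the scaled identity — pass a fraction in [0, 1] or "lw" for the
    Ledoit-Wolf data-driven intensity, which stabilizes distances when the
    reference has barely more observations than score dimensions.
    """
    Q = query.scores if isinstance(query, ScoreMatrix) else np.atleast_2d(np.asarray(query, float))
    if Q.shape[1] < ref.n_components:
        raise ValueError(
            f"query has {Q.shape[1]} components, reference needs {ref.n_components}"
        )
    Q = Q[:, : ref.n_components]
    Sinv = _inverse_covariance(ref, shrinkage)
    diff = Q - ref.mean
    d2 = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    return np.sqrt(np.maximum(d2, 0.0))
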