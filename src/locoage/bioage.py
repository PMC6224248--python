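"""Unsupervised biological age from the activity descriptor.

PCA (on the covariance matrix, no per-variable standardization) of the
64-dimensional log-transition-matrix descriptors of participants aged 40
and older yields a first principal component whose score increases with
chronological age; that score is taken as the biological age.  Biological
age acceleration (BAA) is the residual of the score after ordinary
least-squares detrending on chronological age and gender, i.e. the excess
over the age- and gender-matched expectation.  The same loading vector can
score descriptors from an independent cohort (cross-dataset projection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "BioAgeModel",
    "BAAResult",
    "fit_pca",
    "project",
    "detrend",
    "variance_by_age",
]

TRAINING_MIN_AGE = 40.0


@dataclass
class BioAgeModel:
    """Descriptor mean, first PC loading and detrend coefficients."""

    mean: np.ndarray
    loading: np.ndarray
    explained_variance_ratio: float
    extra_loadings: np.ndarray | None = None
    #: (intercept, age slope, gender offset) once detrend() has been fit
    detrend_coef: np.ndarray | None = None
    training_min_age: float = TRAINING_MIN_AGE

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.loading = np.asarray(self.loading, dtype=float)
        if self.mean.shape != self.loading.shape:
            raise ValueError("mean and loading must have the same length")
        if not np.isclose(np.linalg.norm(self.loading), 1.0):
            raise ValueError("loading must have unit norm")

    def to_json(self, path) -> None:
        d = {
            "mean": self.mean.tolist(),
            "loading": self.loading.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio,
            "detrend_coef": (
                None if self.detrend_coef is None else self.detrend_coef.tolist()
            ),
            "training_min_age": self.training_min_age,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BioAgeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.asarray(d["mean"]),
            loading=np.asarray(d["loading"]),
            explained_variance_ratio=d["explained_variance_ratio"],
            detrend_coef=(
                None
                if d["detrend_coef"] is None
                else np.asarray(d["detrend_coef"])
            ),
            training_min_age=d["training_min_age"],
        )


@dataclass
class BAAResult:
    """Raw scores, detrended scores, and the fitted detrend coefficients."""

    scores: np.ndarray
    baa: np.ndarray
    coef: np.ndarray  # (intercept, age slope, gender offset)
    #: diagnostic: score means in age bins (bin midpoints, means)
    bin_means: tuple[np.ndarray, np.ndarray] | None = None


def fit_pca(
    descriptors: np.ndarray,
    ages: np.ndarray,
    genders: np.ndarray | None = None,
    min_age: float = TRAINING_MIN_AGE,
    n_components: int = 5,
) -> BioAgeModel:
    """Fit the biological-age model on participants aged ``min_age`` and older.

    Mean-centred covariance PCA; the first loading's sign is fixed so that
    the training score correlates non-negatively with age (PCA itself
    leaves the sign free).
    """
    X = np.asarray(descriptors, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if X.ndim != 2 or X.shape[0] != ages.size:
        raise ValueError("descriptors and ages must align")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptors must be finite")
    mask = ages >= min_age
    Xt, at = X[mask], ages[mask]
    if Xt.shape[0] < 2:
        raise ValueError("need at least 2 participants aged above the cutoff")
    if np.allclose(Xt.var(axis=0), 0):
        raise ValueError("descriptors have zero variance")
    pca = PCA(n_components=min(n_components, *Xt.shape))
    scores = pca.fit_transform(Xt)
    loading = pca.components_[0]
    if np.corrcoef(scores[:, 0], at)[0, 1] < 0:
        loading = -loading
    return BioAgeModel(
        mean=pca.mean_,
        loading=loading,
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
        extra_loadings=pca.components_[1:],
        training_min_age=min_age,
    )


def project(model: BioAgeModel, descriptors: np.ndarray) -> np.ndarray:
    """Biological-age scores: projection on the loading about the training mean.

    Works identically for the training cohort and for an independent
    cohort measured with a harmonized alphabet.
    """
    X = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"descriptor length {X.shape[1]} does not match model "
            f"dimension {model.mean.size}"
        )
    return (X - model.mean) @ model.loading


def detrend(
    scores: np.ndarray,
    ages: np.ndarray,
    genders: np.ndarray,
    bin_width: float = 5.0,
) -> BAAResult:
    """Biological age acceleration: OLS residual of score on age and gender.

    The residuals have exactly zero mean and zero linear correlation with
    age and gender on the fitting set, and are invariant under adding a
    constant to every age.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    genders = np.asarray(genders, dtype=float)
    if scores.size <= 3:
        raise ValueError("need more than 3 observations to detrend")
    if np.ptp(ages) == 0:
        raise ValueError("constant age column; detrending is degenerate")
    X = np.column_stack([np.ones_like(ages), ages, genders])
    coef, *_ = np.linalg.lstsq(X, scores, rcond=None)
    baa = scores - X @ coef
    edges = np.arange(ages.min(), ages.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(ages, edges) - 1, 0, edges.size - 2)
    mids, means = [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.sum() > 0:
            mids.append(edges[b] + bin_width / 2)
            means.append(scores[sel].mean())
    return BAAResult(
        scores=scores,
        baa=baa,
        coef=coef,
        bin_means=(np.asarray(mids), np.asarray(means)),
    )


def variance_by_age(
    scores: np.ndarray,
    ages: np.ndarray,
    bin_width: float = 5.0,
    min_bin_n: int = 10,
) -> dict:
    """Score variance per age bin and the slope of variance vs bin age.

    A positive slope is the diffusion signature: the spread of biological
    age in age-matched cohorts grows with chronological age.  Within each
    bin the scores are detrended on age before taking the variance, so the
    aging drift across a bin's width does not leak into the spread and the
    estimate is stable under changes of bin width; the bin's x-coordinate
    is its members' mean age (edge bins may cover only part of their
    nominal range).  Returns bin positions, variances, counts, the OLS
    slope and its standard error.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    edges = np.arange(ages.min(), ages.max() + bin_width, bin_width)
    mids, variances, counts = [], [], []
    for b in range(edges.size - 1):
        sel = (ages >= edges[b]) & (ages < edges[b + 1])
        if sel.sum() >= min_bin_n:
            a, s = ages[sel], scores[sel]
            coef = np.polyfit(a, s, 1) if np.ptp(a) > 0 else np.array([0.0, s.mean()])
            resid = s - np.polyval(coef, a)
            mids.append(a.mean())
            variances.append(resid @ resid / max(sel.sum() - 2, 1))
            counts.append(int(sel.sum()))
    if len(mids) < 2:
        raise ValueError("need at least 2 populated age bins")
    mids = np.asarray(mids)
    variances = np.asarray(variances)
    X = np.column_stack([np.ones_like(mids), mids])
    coef, res, *_ = np.linalg.lstsq(X, variances, rcond=None)
    resid = variances - X @ coef
    dof = max(mids.size - 2, 1)
    s2 = (resid**2).sum() / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return {
        "bin_mid": mids,
        "variance": variances,
        "n": np.asarray(counts),
        "slope": float(coef[1]),
        "slope_se": float(np.sqrt(cov[1, 1])),
    }
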