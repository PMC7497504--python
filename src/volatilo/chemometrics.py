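"""Chemometric layer: PCA, Ward clustering, NIPALS PLSR and figures of merit.

The calibration task is to predict the alpha-acid content (% w/w) of a hop
sample from its unfolded spectral fingerprint.  The workflow mirrors common
chemometric practice:

* PCA for dimension reduction and score-plot inspection, with 97.5 %
  Mahalanobis ellipses per alpha-acid group;
* agglomerative hierarchical clustering (Ward's minimum-variance criterion,
  Euclidean distances) on the first five PC scores;
* PLS regression fitted by the classical NIPALS algorithm for univariate y,
  with a single external train/test split (rank-stratified so the test set
  covers the calibration range without containing a global extreme) and
  stepwise latent-variable selection;
* figures of merit: R^2 and RMSEC on the training fit, RMSEP, Bias, SEP and
  the relative percentage error RE on the external test set,

    RMSEP = sqrt( sum (c_i - c_i^pred)^2 / n )
    Bias  = sum (c_i - c_i^pred) / n
    SEP   = sqrt( sum (c_i - c_i^pred - Bias)^2 / (n - 1) )
    RE%   = 100 * sqrt( sum (c_i - c_i^pred)^2 / sum c_i^2 )

  which satisfy RMSEP^2 = Bias^2 + SEP^2 * (n-1)/n identically.

Loading vectors and regression coefficients can be refolded onto the
(RT, drift-time) or (RT, m/z) plane to locate the compounds that carry the
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import chi2

from .preprocess import ColumnScaler, UnfoldedMatrix


# --------------------------------------------------------------------------
# alpha-acid grouping

#: Group thresholds in % w/w: low 1-6.9, middle 7.0-10, high above 10.
ALPHA_GROUP_BOUNDS = {"low": 6.9, "middle": 10.0}


def assign_alpha_group(alpha: float) -> str:
    """Classify an alpha-acid content (% w/w) as low / middle / high.

    Values are rounded to one decimal first so the gap between 6.9 and 7.0
    cannot fall between the groups.
    """
    if alpha < 0:
        raise ValueError("alpha-acid content cannot be negative")
    a = round(float(alpha), 1)
    if a <= ALPHA_GROUP_BOUNDS["low"]:
        return "low"
    if a <= ALPHA_GROUP_BOUNDS["middle"]:
        return "middle"
    return "high"


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    loadings: np.ndarray  # (n_components, n_features), rows orthonormal
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_pct: np.ndarray
    means: np.ndarray  # column means used for centering

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        return (np.asarray(X_new, dtype=float) - self.means) @ self.loadings.T


def pca_fit(X, n_components: int, center: bool = True) -> PCAModel:
    """Principal component analysis by singular value decomposition.

    Components are ordered by decreasing variance; the explained variance of
    a component is its score variance as a percentage of the total variance
    of the (centered) matrix, so a truncated model sums to <= 100 %.
    ``X`` may be an :class:`UnfoldedMatrix` or a plain 2D array.
    """
    A = X.X if isinstance(X, UnfoldedMatrix) else np.asarray(X, dtype=float)
    n, p = A.shape
    if not 1 <= n_components <= min(n - 1 if center else n, p):
        raise ValueError("n_components must be within min(n-1, p)")
    means = A.mean(axis=0) if center else np.zeros(p)
    Ac = A - means
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    total_var = float((Ac**2).sum()) / max(n - 1, 1)
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    ev = (s[:n_components] ** 2 / max(n - 1, 1)) / total_var * 100.0
    return PCAModel(loadings=loadings, scores=scores,
                    explained_variance_pct=ev, means=means)


# --------------------------------------------------------------------------
# hierarchical clustering

@dataclass
class DendrogramResult:
    """Ward/Euclidean agglomeration over samples (scipy linkage encoding).

    ``merges`` holds one row per merge: (cluster_a, cluster_b, height, size);
    heights are non-decreasing (Ward is reducible, hence monotone).
    """

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    n_samples: int
    linkage: str = "ward"
    metric: str = "euclidean"

    def cut(self, n_clusters: int | None = None, height: float | None = None
            ) -> np.ndarray:
        """Flat cluster labels at a cluster count or a merge height."""
        if (n_clusters is None) == (height is None):
            raise ValueError("give exactly one of n_clusters or height")
        if n_clusters is not None:
            return hierarchy.fcluster(self.merges, n_clusters, criterion="maxclust")
        return hierarchy.fcluster(self.merges, height, criterion="distance")


def hca_ward(scores: np.ndarray, k: int | None = 5) -> DendrogramResult:
    """Ward's minimum-variance clustering on the first ``k`` PC scores.

    ``k=None`` uses all supplied columns.  Heights follow scipy's Ward
    convention (the Euclidean merge distance whose square is proportional to
    the increase in within-cluster variance).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        S = S[:, :k]
    Z = hierarchy.linkage(S, method="ward", metric="euclidean")
    return DendrogramResult(merges=Z, n_samples=S.shape[0])


# --------------------------------------------------------------------------
# train/test split

def split_train_test(
    y: np.ndarray, n_test: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-stratified external split covering the calibration range.

    Samples are ordered by response; the global minimum and maximum are
    reserved for training (so test predictions are interpolations), the
    remaining order statistics are divided into ``n_test`` contiguous strata
    and one test sample is drawn per stratum.  Deterministic under ``seed``.
    Returns (train indices, test indices).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 1 <= n_test < n:
        raise ValueError("n_test must be in [1, n)")
    if n_test > n - 2:
        raise ValueError("n_test leaves no room to retain the extremes in training")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    interior = order[1:-1]
    strata = np.array_split(interior, n_test)
    test = np.array(sorted(int(s[rng.integers(len(s))]) for s in strata))
    train = np.array(sorted(set(range(n)) - set(test.tolist())))
    return train, test


# --------------------------------------------------------------------------
# PLSR (NIPALS)

class RankError(ValueError):
    """More latent variables requested than the training matrix supports."""


@dataclass
class PLSRModel:
    """PLS1 regression model fitted by NIPALS.

    Stores the weight/score/loading matrices per latent variable, the
    regression vector on the preprocessed feature scale, and the training
    preprocessing parameters (column centering, optional Pareto scaling) so
    new samples are transformed exactly as the training set was.
    """

    n_lv: int
    weights: np.ndarray  # (p, n_lv) X-weights w_k
    x_loadings: np.ndarray  # (p, n_lv)
    y_loadings: np.ndarray  # (n_lv,)
    x_scores: np.ndarray  # (n_train, n_lv)
    coef: np.ndarray  # (p,) regression vector on preprocessed features
    scaler: ColumnScaler = field(repr=False, default=None)  # type: ignore[assignment]
    y_mean: float = 0.0

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        Xc = self.scaler.transform(np.atleast_2d(np.asarray(X_new, dtype=float)))
        return Xc @ self.coef + self.y_mean


def plsr_fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_lv: int,
    pareto: bool = False,
) -> PLSRModel:
    """Fit a PLS1 model by NIPALS with sequential deflation.

    Per latent variable: the X-weight is the covariance direction
    ``w = X'y / ||X'y||``, scores ``t = Xw``, loadings ``p = X't/t't`` and
    ``q = y't/t't``, then X and y are deflated by the extracted component.
    The regression vector is ``B = W (P'W)^(-1) q``.  Columns are centered
    (optionally Pareto-scaled) internally and the parameters stored.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of samples")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    scaler = ColumnScaler(pareto=pareto).fit(X)
    Xc = scaler.transform(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    rank_cap = min(X.shape[0] - 1, X.shape[1])
    if n_lv > rank_cap:
        raise RankError(f"n_lv={n_lv} exceeds the matrix rank bound {rank_cap}")
    p_feat = X.shape[1]
    W = np.zeros((p_feat, n_lv))
    P = np.zeros((p_feat, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((X.shape[0], n_lv))
    Xk, yk = Xc.copy(), yc.copy()
    eps = np.finfo(float).eps
    for k in range(n_lv):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw <= eps * max(1.0, np.abs(yk).max(initial=0.0)) * p_feat:
            raise RankError(f"residual covariance vanished after {k} latent variables")
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= eps:
            raise RankError(f"degenerate score vector at latent variable {k + 1}")
        p_vec = Xk.T @ t / tt
        q_k = float(yk @ t) / tt
        Xk = Xk - np.outer(t, p_vec)
        yk = yk - q_k * t
        W[:, k], P[:, k], q[k], T[:, k] = w, p_vec, q_k, t
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(n_lv=n_lv, weights=W, x_loadings=P, y_loadings=q,
                     x_scores=T, coef=coef, scaler=scaler, y_mean=y_mean)


def plsr_predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for new samples with a fitted PLS model."""
    return model.predict(X_new)


@dataclass
class LVSelection:
    n_lv: int
    rmsec: np.ndarray  # indexed by n_lv - 1
    rmsep: np.ndarray
    overfit_flag: bool
    flat_flag: bool


def select_lv(
    X_train, y_train, X_test, y_test,
    lv_max: int = 10, pareto: bool = False, tol: float = 0.05,
) -> LVSelection:
    """Stepwise latent-variable selection against the external test set.

    Fits models with 1..lv_max latent variables, records RMSEC and RMSEP per
    count, and returns the smallest count whose RMSEP lies within ``tol``
    (relative) of the minimum — a parsimony rule formalising "increase LVs
    while validation keeps improving".  Flags overfitting when RMSEP rises
    while RMSEC still falls, and warns when the validation curve is flat
    (no real gain over a single component).
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    lv_max = max(1, min(lv_max, min(np.asarray(X_train).shape) - 1))
    rmsec_list: list[float] = []
    rmsep_list: list[float] = []
    for k in range(1, lv_max + 1):
        try:
            m = plsr_fit(X_train, y_train, k, pareto=pareto)
        except RankError:
            break  # residual rank exhausted; curve ends here
        rmsec_list.append(_rms(y_train - m.predict(X_train)))
        rmsep_list.append(_rms(y_test - m.predict(X_test)))
    rmsec = np.array(rmsec_list)
    rmsep = np.array(rmsep_list)
    best = int(np.argmin(rmsep))
    chosen = int(np.nonzero(rmsep <= rmsep[best] * (1 + tol))[0][0]) + 1
    overfit = bool(np.any((np.diff(rmsep) > 0) & (np.diff(rmsec) < 0)))
    flat = bool(rmsep[best] >= rmsep[0] * (1 - tol))
    if flat:
        warnings.warn("validation error is flat across latent variables; "
                      "the response may be uncorrelated with the features",
                      stacklevel=2)
    return LVSelection(n_lv=chosen, rmsec=rmsec, rmsep=rmsep,
                       overfit_flag=overfit, flat_flag=flat)


# --------------------------------------------------------------------------
# figures of merit

def _rms(resid: np.ndarray) -> float:
    resid = np.asarray(resid, dtype=float)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass
class MeritReport:
    """Calibration / prediction figures of merit (% alpha-acid units)."""

    r2: float
    rmsec: float
    rmsep: float
    bias: float
    sep: float
    re_pct: float
    n_train: int = 0
    n_test: int = 0

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmsec": self.rmsec, "rmsep": self.rmsep,
                "bias": self.bias, "sep": self.sep, "re_pct": self.re_pct,
                "n_train": self.n_train, "n_test": self.n_test}


def figures_of_merit(
    y_train: np.ndarray, fitted: np.ndarray,
    y_test: np.ndarray, predicted: np.ndarray,
) -> MeritReport:
    """R^2/RMSEC on the training fit, RMSEP/Bias/SEP/RE on the test set.

    R^2 is the determination coefficient of the calibration (1 minus the
    ratio of residual to total sum of squares of the training responses);
    SEP is the bias-corrected standard deviation of the test residuals with
    an n-1 denominator; RE is the root of the squared-error sum relative to
    the squared test responses, in percent.
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    fitted = np.asarray(fitted, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if len(y_train) != len(fitted) or len(y_test) != len(predicted):
        raise ValueError("response and prediction lengths differ")
    if len(y_test) < 2:
        raise ValueError("SEP needs at least two test samples")
    ss_res = float(np.sum((y_train - fitted) ** 2))
    ss_tot = float(np.sum((y_train - y_train.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmsec = _rms(y_train - fitted)
    resid = y_test - predicted
    n = len(y_test)
    rmsep = _rms(resid)
    bias = float(resid.mean())
    sep = float(np.sqrt(np.sum((resid - bias) ** 2) / (n - 1)))
    re_pct = float(100.0 * np.sqrt(np.sum(resid**2) / np.sum(y_test**2)))
    return MeritReport(r2=r2, rmsec=rmsec, rmsep=rmsep, bias=bias, sep=sep,
                       re_pct=re_pct, n_train=len(y_train), n_test=n)


# --------------------------------------------------------------------------
# Mahalanobis group ellipses

@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_deg: float  # orientation of the major axis
    level: float
    threshold: float  # chi^2 quantile on the squared Mahalanobis distance


def mahalanobis_ellipse(scores_2d: np.ndarray, level: float = 0.975) -> Ellipse:
    """Confidence ellipse of one group in a 2D score plane.

    The boundary is the contour where the squared Mahalanobis distance to the
    group mean equals the chi-square quantile with 2 degrees of freedom at
    ``level`` (7.378 at 97.5 %).
    """
    S = np.asarray(scores_2d, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if S.shape[0] < 3:
        raise ValueError("need at least three points for a covariance ellipse")
    center = S.mean(axis=0)
    cov = np.cov(S, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 0:
        raise np.linalg.LinAlgError("degenerate group: singular covariance")
    thr = float(chi2.ppf(level, df=2))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   semi_axes=(float(np.sqrt(evals[0] * thr)),
                              float(np.sqrt(evals[1] * thr))),
                   angle_deg=angle, level=level, threshold=thr)


def squared_mahalanobis(scores_2d: np.ndarray, point: np.ndarray) -> float:
    S = np.asarray(scores_2d, dtype=float)
    mu = S.mean(axis=0)
    cov = np.cov(S, rowvar=False)
    d = np.asarray(point, dtype=float) - mu
    return float(d @ np.linalg.solve(cov, d))


# --------------------------------------------------------------------------
# loading refolding

def refold_loadings(vector: np.ndarray, matrix: UnfoldedMatrix) -> np.ndarray:
    """Refold a loading / regression vector onto the 2D spectral plane."""
    return matrix.refold(vector)


def top_features(
    vector: np.ndarray, matrix: UnfoldedMatrix, n_top: int = 10,
) -> list[tuple[float, float, float]]:
    """Coordinates (rt, axis2, weight) of the largest-|weight| features."""
    v = np.asarray(vector).ravel()
    if v.size != matrix.n_features:
        raise ValueError("vector length does not match the column map")
    idx = np.argsort(np.abs(v))[::-1][:n_top]
    return [(*matrix.column_coords(int(j)), float(v[j])) for j in idx]


def annotate_top_features(
    vector: np.ndarray, matrix: UnfoldedMatrix, n_top: int = 10,
    library=None, rt_tol: float = 0.1, dt_tol: float = 0.01,
) -> list[tuple[float, float, float, str]]:
    """Top loading coordinates with compound names from the drift library.

    Only meaningful for drift-time matrices; each (rt, dt_rel, weight)
    triple gains the name of the matching reference entry or "unknown".
    """
    from . import mobility

    tops = top_features(vector, matrix, n_top)
    peaks = [mobility.Peak(rt=rt, dt_rel=dt, intensity=abs(w))
             for rt, dt, w in tops]
    anns = mobility.annotate(peaks, library, rt_tol=rt_tol, dt_tol=dt_tol)
    return [(rt, dt, w, ann.name) for (rt, dt, w), ann in zip(tops, anns)]
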