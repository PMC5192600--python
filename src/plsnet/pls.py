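"""SIMPLS partial least squares and VIP feature scoring.

This module solves a single univariate regression subproblem: given a
centered design matrix ``X`` (conditions x candidate regulators) and a
centered response ``y`` (the target gene's expression), it extracts up to
``m`` PLS components and converts the fitted directions into per-feature
variable-importance-in-projection (VIP) scores.

The solver follows the SIMPLS construction: component ``i`` maximizes the
squared covariance ``cov^2(X v_i, y)`` over unit-norm directions ``v_i``
subject to the score vectors ``P_i = X v_i`` being orthogonal to all earlier
ones.  Directions act on the *original* (undeflated) design, which is what
makes the VIP weights directly interpretable per feature.

VIP for feature ``j`` is

    VIP_j = sqrt( p * sum_i psi_i * v_ji^2 / sum_i psi_i )

where ``psi_i = r^2(y, P_i)`` is the squared Pearson correlation between the
response and the i-th component score vector and ``p`` is the number of
features.  With unit-norm directions the squared VIPs always sum to ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateInputError, DimensionError

__all__ = [
    "PLSModel",
    "VIPResult",
    "SIMPLS",
    "center",
    "simpls_fit",
    "explained_variation",
    "vip_scores",
    "plsfs",
]

# Extraction stops once the residual covariance norm falls below this
# fraction of its initial norm (the constraint set of the SIMPLS objective
# becomes numerically infeasible beyond the effective rank).
RELATIVE_TRUNCATION = 1e-12


# ---------------------------------------------------------------------------
# plain-array core
# ---------------------------------------------------------------------------


def center(matrix, response=None):
    """Column-center a design matrix and (optionally) a response vector.

    Returns copies with exact zero column means; values are otherwise
    unchanged.  Centering an already-centered input is the identity.

    Raises
    ------
    DimensionError
        If ``matrix`` and ``response`` have different numbers of rows, or
        fewer than 2 rows are supplied.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise DimensionError(f"design matrix must be 2-D, got ndim={X.ndim}")
    if X.shape[0] < 2:
        raise DimensionError("need at least 2 observations to center")
    Xc = X - X.mean(axis=0)
    if response is None:
        return Xc
    y = np.asarray(response, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise DimensionError(
            f"design has {X.shape[0]} rows but response has {y.shape[0]} entries"
        )
    return Xc, y - y.mean()


def _simpls_core(Xc, yc, n_components):
    """Extract up to ``n_components`` SIMPLS components from centered data.

    Returns ``(directions, scores, psi)`` with shapes ``(p, k)``, ``(n, k)``
    and ``(k,)`` where ``k <= n_components`` is the number of components
    actually extracted.  Returns ``k = 0`` when the initial covariance
    vanishes (degenerate input).
    """
    n, p = Xc.shape
    s = Xc.T @ yc  # covariance direction (up to 1/(n-1))
    norm0 = np.linalg.norm(s)
    if not np.isfinite(norm0) or norm0 == 0.0:
        return np.empty((p, 0)), np.empty((n, 0)), np.empty(0)

    y_ss = yc @ yc
    directions: list[np.ndarray] = []
    scores: list[np.ndarray] = []
    psi: list[float] = []
    basis: list[np.ndarray] = []  # orthonormal loading basis for deflation

    for _ in range(n_components):
        s_norm = np.linalg.norm(s)
        if s_norm <= RELATIVE_TRUNCATION * norm0:
            break
        v = s / s_norm
        t = Xc @ v
        tt = t @ t
        if tt <= 0.0:
            break
        # sign convention: largest-magnitude entry of the direction positive
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
            t = -t
        # explained variation of this component: squared correlation with y
        # (t has zero mean because Xc is column-centered)
        r2 = float((t @ yc) ** 2 / (tt * y_ss)) if y_ss > 0 else 0.0
        if r2 <= 0.0:
            # a component carrying no response information ends extraction
            directions.append(v)
            scores.append(t)
            psi.append(0.0)
            break
        directions.append(v)
        scores.append(t)
        psi.append(min(r2, 1.0))
        # deflate the covariance against the loading of this score vector
        load = Xc.T @ t / tt
        for u in basis:
            load = load - u * (u @ load)
        load_norm = np.linalg.norm(load)
        if load_norm <= RELATIVE_TRUNCATION:
            break
        u = load / load_norm
        basis.append(u)
        s = s - u * (u @ s)

    k = len(directions)
    if k == 0:
        return np.empty((p, 0)), np.empty((n, 0)), np.empty(0)
    return np.column_stack(directions), np.column_stack(scores), np.asarray(psi)


def _vip_from_fit(directions, psi):
    """VIP scores from unit-norm directions (p, k) and psi weights (k,).

    Returns ``(scores, degenerate)``; all-zero scores with the degenerate
    flag set when no component correlates with the response.
    """
    p = directions.shape[0]
    total = float(psi.sum())
    if directions.shape[1] == 0 or total <= 0.0:
        return np.zeros(p), True
    return np.sqrt(p * (directions**2 @ psi) / total), False


def _simpls_vip(Xc, yc, n_components):
    """Fast path for the ensemble loop: centered arrays in, VIP out.

    Returns ``None`` for a degenerate fit (no covariance with the response).
    """
    directions, _, psi = _simpls_core(Xc, yc, n_components)
    scores, degenerate = _vip_from_fit(directions, psi)
    return None if degenerate else scores


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PLSModel:
    """Fitted SIMPLS state for a single subproblem.

    Attributes
    ----------
    directions : (p, m) array
        Unit-norm direction vectors, one column per component.
    components : (n, m) array
        Score vectors ``P_i = X v_i``; mutually orthogonal.
    explained : (m,) array
        ``psi_i = r^2(y, P_i)``, each in [0, 1].
    n_components : int
        Number of components actually extracted (may be fewer than
        requested if the residual covariance vanished early).
    feature_ids : tuple of str, optional
        Column labels aligned with ``directions`` rows.
    """

    directions: np.ndarray
    components: np.ndarray
    explained: np.ndarray
    n_components: int
    feature_ids: tuple | None = None

    @property
    def truncated(self) -> bool:
        """Whether fewer components were extracted than requested."""
        return bool(self.n_components < getattr(self, "_requested", self.n_components))


@dataclass(frozen=True)
class VIPResult:
    """Per-feature VIP scores with a degenerate-fit flag.

    ``degenerate`` is True when no component carried response information
    (sum of psi is zero, e.g. a constant response); scores are then all
    zero so ensemble iterations can skip silently.
    """

    scores: np.ndarray
    feature_ids: tuple | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simpls_fit(matrix, response, n_components, feature_ids=None) -> PLSModel:
    """Fit a SIMPLS model on *centered* inputs.

    Parameters
    ----------
    matrix : (n, p) array-like
        Centered design matrix.
    response : (n,) array-like
        Centered response vector.
    n_components : int
        Requested number of components ``m >= 1``.  The returned model may
        hold fewer if the residual covariance vanishes early.

    Raises
    ------
    ValueError
        If ``n_components < 1``.
    DegenerateInputError
        If the design carries no covariance with the response (e.g.
        all-zero design or constant response).
    """
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise DimensionError(
            f"design has {X.shape[0]} rows but response has {y.shape[0]} entries"
        )
    directions, scores, psi = _simpls_core(X, y, n_components)
    if directions.shape[1] == 0:
        raise DegenerateInputError(
            "design matrix has no covariance with the response; "
            "cannot extract any PLS component"
        )
    model = PLSModel(
        directions=directions,
        components=scores,
        explained=psi,
        n_components=directions.shape[1],
        feature_ids=tuple(feature_ids) if feature_ids is not None else None,
    )
    object.__setattr__(model, "_requested", int(n_components))
    return model


def explained_variation(model: PLSModel, response) -> np.ndarray:
    """Squared Pearson correlation between the response and each component.

    A component with zero variance gets psi = 0.
    """
    y = np.asarray(response, dtype=float).ravel()
    if model.components.shape[0] != y.shape[0]:
        raise DimensionError(
            f"components have {model.components.shape[0]} rows but response "
            f"has {y.shape[0]} entries"
        )
    yc = y - y.mean()
    y_ss = yc @ yc
    out = np.zeros(model.n_components)
    if y_ss <= 0:
        return out
    for i in range(model.n_components):
        t = model.components[:, i]
        tc = t - t.mean()
        tt = tc @ tc
        if tt > 0:
            out[i] = min(float((tc @ yc) ** 2 / (tt * y_ss)), 1.0)
    return out


def vip_scores(model: PLSModel, response) -> VIPResult:
    """VIP score per feature; squared scores sum to p for non-degenerate fits."""
    psi = explained_variation(model, response)
    scores, degenerate = _vip_from_fit(model.directions, psi)
    return VIPResult(scores=scores, feature_ids=model.feature_ids, degenerate=degenerate)


def plsfs(matrix, response, n_components, feature_ids=None, scale=False) -> VIPResult:
    """PLS-based feature selection: center -> SIMPLS -> VIP.

    Degenerate inputs (constant response, zero design) yield all-zero
    scores with the ``degenerate`` flag set instead of raising, so that
    ensemble iterations over bootstrap resamples can skip them silently.
    """
    Xc, yc = center(matrix, response)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    p = Xc.shape[1]
    ids = tuple(feature_ids) if feature_ids is not None else None
    try:
        model = simpls_fit(Xc, yc, n_components)
    except DegenerateInputError:
        return VIPResult(scores=np.zeros(p), feature_ids=ids, degenerate=True)
    result = vip_scores(model, yc)
    return VIPResult(scores=result.scores, feature_ids=ids, degenerate=result.degenerate)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class SIMPLS(RegressorMixin, BaseEstimator):
    """SIMPLS partial-least-squares regression with VIP feature importances.

    Parameters
    ----------
    n_components : int, default=2
        Number of PLS components to extract.  The fitted model may hold
        fewer (``n_components_``) if the covariance is exhausted early.
    center : bool, default=True
        Subtract column means before fitting (the model assumes zero-mean
        inputs; disable only if the data are already centered).
    scale : bool, default=False
        Additionally divide columns by their sample standard deviation.
        VIP is scale-sensitive; the default keeps raw scale.

    Attributes
    ----------
    x_weights_ : (p, n_components_) ndarray
        Unit-norm direction vectors.
    x_scores_ : (n, n_components_) ndarray
        Component score vectors, mutually orthogonal.
    explained_variation_ : (n_components_,) ndarray
        Squared correlation of each component with the response.
    vip_ : (p,) ndarray
        VIP importance per feature; squared values sum to ``p``.
    degenerate_ : bool
        True when no component correlated with the response; ``vip_`` is
        then all zero and ``predict`` returns the response mean.
    coef_ : (p,) ndarray
        Regression coefficients on (centered, optionally scaled) inputs.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(50, 4))
    >>> y = 2.0 * X[:, 1] + rng.normal(scale=0.1, size=50)
    >>> model = SIMPLS(n_components=2).fit(X, y)
    >>> int(np.argmax(model.vip_))
    1
    """

    def __init__(self, n_components=2, center=True, scale=False):
        self.n_components = n_components
        self.center = center
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise DimensionError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if self.n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {self.n_components}")

        self.x_mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        self.y_mean_ = y.mean() if self.center else 0.0
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.x_scale_ = sd
            Xc = Xc / sd
        else:
            self.x_scale_ = np.ones(X.shape[1])

        m_max = min(self.n_components, X.shape[1], X.shape[0] - 1)
        directions, scores, psi = _simpls_core(Xc, yc, m_max)
        self.x_weights_ = directions
        self.x_scores_ = scores
        self.explained_variation_ = psi
        self.n_components_ = directions.shape[1]
        self.vip_, self.degenerate_ = _vip_from_fit(directions, psi)
        # least-squares response weight per orthogonal component
        if self.n_components_ > 0:
            ss = np.einsum("ij,ij->j", scores, scores)
            q = (scores.T @ yc) / ss
            self.coef_ = directions @ q
        else:
            self.coef_ = np.zeros(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xc = (X - self.x_mean_) / self.x_scale_
        return Xc @ self.coef_ + self.y_mean_

    def to_model(self) -> PLSModel:
        """Export the fitted state as a :class:`PLSModel`."""
        return PLSModel(
            directions=self.x_weights_,
            components=self.x_scores_,
            explained=self.explained_variation_,
            n_components=self.n_components_,
        )
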