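"""Generalized partial credit model (GPCM) probability machinery.

The GPCM is a divide-by-total IRT model for ordered polytomous responses.
For an item with ``c`` categories internally scored ``x = 0..c-1``, a person
with trait value ``theta`` responds in category ``x`` with probability

    P(x) = exp( sum_{j<=x} alpha * (theta - tau_j) ) / sum_k exp( ... )

where the empty sum (``x = 0``) is zero, ``alpha`` is the item slope and
``tau_1..tau_{c-1}`` are the category thresholds.  Equivalently, using
cumulative category intercepts ``d_x = -alpha * sum_{j<=x} tau_j`` (with
``d_0 = 0``),

    P(x) ∝ exp( x * alpha * theta + d_x ).

The intercept form is numerically convenient (it stays well defined for
slopes arbitrarily close to zero) and is the parameterization used by the
sampler; both forms are exposed here with exact converters.

External data are coded ``1..c`` with a configurable missing code; all
internal scoring is ``0..c-1``.  The :class:`ResponseMatrix` owns that
conversion boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = [
    "ResponseMatrix",
    "GpcmParameters",
    "LatentAbility",
    "category_probabilities",
    "category_logits",
    "log_likelihood",
    "thresholds_to_intercepts",
    "intercepts_to_thresholds",
]


@dataclass
class ResponseMatrix:
    """N persons x K items of ordinal responses coded ``1..c``.

    ``responses`` holds integer categories; entries where ``missing_mask``
    is true are ignored everywhere (their stored value is irrelevant but
    kept at 0 by convention).
    """

    responses: np.ndarray
    c: int = 4
    missing_mask: np.ndarray | None = None
    person_ids: list | None = None
    item_ids: list | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D person x item matrix")
        n, k = self.responses.shape
        if n < 1 or k < 1:
            raise ValueError("need at least one person and one item")
        if self.c < 3:
            raise ValueError(f"category count must be >= 3, got {self.c}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, k), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, k):
                raise ValueError("missing_mask shape does not match responses")
        obs = self.responses[~self.missing_mask]
        if obs.size:
            if not np.issubdtype(np.asarray(obs).dtype, np.integer):
                if not np.allclose(obs, np.round(obs)):
                    raise ValueError("non-integer response categories")
            if obs.min() < 1 or obs.max() > self.c:
                bad = np.argwhere(
                    (~self.missing_mask)
                    & ((self.responses < 1) | (self.responses > self.c))
                )[0]
                raise ValueError(
                    f"response out of range [1, {self.c}] at cell "
                    f"(person {bad[0]}, item {bad[1]})"
                )
        self.responses = np.where(self.missing_mask, 0, self.responses).astype(np.int64)
        if self.person_ids is None:
            self.person_ids = [f"p{i + 1}" for i in range(n)]
        if self.item_ids is None:
            self.item_ids = [f"item{i + 1}" for i in range(k)]

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def scores(self) -> np.ndarray:
        """Internal 0-based scores (missing cells hold 0; mask applies)."""
        return np.where(self.missing_mask, 0, self.responses - 1)

    @property
    def observed(self) -> np.ndarray:
        """Boolean matrix, true where a response is present."""
        return ~self.missing_mask

    def is_extreme(self) -> np.ndarray:
        """Boolean matrix: observed response in the bottom or top category."""
        return self.observed & ((self.responses == 1) | (self.responses == self.c))


@dataclass
class GpcmParameters:
    """Item parameters of a (multidimensional between-item) GPCM.

    ``intercepts`` is K x c with the category-0 column fixed at zero;
    ``dim_of_item`` maps each item to the single substantive dimension it
    loads on (0-based).  ``trait_correlation`` is the V x V correlation
    matrix of the latent traits (identity for V = 1).
    """

    slopes: np.ndarray
    intercepts: np.ndarray
    dim_of_item: np.ndarray | None = None
    trait_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.slopes = np.atleast_1d(np.asarray(self.slopes, dtype=float))
        self.intercepts = np.atleast_2d(np.asarray(self.intercepts, dtype=float))
        k, c = self.intercepts.shape
        if self.slopes.shape != (k,):
            raise ValueError("slopes length must match intercept rows")
        if not np.all(self.intercepts[:, 0] == 0.0):
            raise ValueError("category-0 intercept must be fixed at zero")
        if self.dim_of_item is None:
            self.dim_of_item = np.zeros(k, dtype=np.int64)
        else:
            self.dim_of_item = np.asarray(self.dim_of_item, dtype=np.int64)
        v = int(self.dim_of_item.max()) + 1
        if self.trait_correlation is None:
            self.trait_correlation = np.eye(v)
        else:
            self.trait_correlation = np.asarray(self.trait_correlation, dtype=float)
            r = self.trait_correlation
            if r.shape[0] != r.shape[1] or not np.allclose(r, r.T):
                raise ValueError("trait correlation must be square symmetric")
            if not np.allclose(np.diag(r), 1.0):
                raise ValueError("trait correlation must have unit diagonal")
            np.linalg.cholesky(r)  # raises if not positive definite

    @property
    def n_items(self) -> int:
        return self.slopes.shape[0]

    @property
    def c(self) -> int:
        return self.intercepts.shape[1]

    @property
    def n_dims(self) -> int:
        return self.trait_correlation.shape[0]

    @property
    def thresholds(self) -> np.ndarray:
        """K x (c-1) threshold matrix; requires nonzero slopes."""
        return np.stack(
            [
                intercepts_to_thresholds(self.intercepts[i], self.slopes[i])
                for i in range(self.n_items)
            ]
        )


@dataclass
class LatentAbility:
    """Person trait values on the standard-normal scale, N x V."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite trait values")


def thresholds_to_intercepts(thresholds: np.ndarray, slope: float) -> np.ndarray:
    """Map thresholds ``tau_1..tau_{c-1}`` to cumulative intercepts ``d_0..d_{c-1}``.

    ``d_x = -slope * sum_{j<=x} tau_j`` with ``d_0 = 0``.
    """
    tau = np.asarray(thresholds, dtype=float)
    if tau.ndim != 1:
        raise ValueError("thresholds must be a vector")
    return np.concatenate([[0.0], -slope * np.cumsum(tau)])


def intercepts_to_thresholds(intercepts: np.ndarray, slope: float) -> np.ndarray:
    """Inverse of :func:`thresholds_to_intercepts`; undefined at slope zero."""
    d = np.asarray(intercepts, dtype=float)
    if d[0] != 0.0:
        raise ValueError("category-0 intercept must be zero")
    if slope == 0.0:
        if np.any(d != 0.0):
            raise ValueError("thresholds undefined: slope is zero with nonzero intercepts")
        warnings.warn("slope is zero; returning zero thresholds", stacklevel=2)
        return np.zeros(d.shape[0] - 1)
    return -np.diff(d) / slope


def category_probabilities(theta: float, slope: float, thresholds: np.ndarray) -> np.ndarray:
    """GPCM category probabilities for one person-item pair.

    Returns a length-``c`` vector over categories scored 0..c-1 (externally
    coded 1..c).  Evaluated through log-sum-exp so cumulative logits up to
    a few hundred in magnitude are handled without overflow.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if not (np.isfinite(theta) and np.isfinite(slope) and np.all(np.isfinite(thresholds))):
        raise ValueError("non-finite GPCM inputs")
    cum = np.concatenate([[0.0], np.cumsum(slope * (theta - thresholds))])
    return softmax(cum)


def category_logits(
    theta: np.ndarray,
    params: GpcmParameters,
) -> np.ndarray:
    """Unnormalized category log-probabilities, N x K x c.

    ``logit[n, i, x] = x * slope_i * theta[n, dim(i)] + d_{i,x}``.
    """
    theta = np.atleast_2d(theta)
    th_item = theta[:, params.dim_of_item]  # N x K
    x = np.arange(params.c, dtype=float)
    return (
        x[None, None, :] * (params.slopes[None, :] * th_item)[:, :, None]
        + params.intercepts[None, :, :]
    )


def category_probabilities_matrix(theta: np.ndarray, params: GpcmParameters) -> np.ndarray:
    """Normalized N x K x c category probability tensor."""
    return softmax(category_logits(theta, params), axis=-1)


def log_likelihood(
    data: ResponseMatrix, params: GpcmParameters, ability: LatentAbility
) -> float:
    """Joint log-likelihood over the observed (non-missing) cells."""
    if params.n_items != data.n_items:
        raise ValueError("item count mismatch between data and parameters")
    if ability.theta.shape[0] != data.n_persons:
        raise ValueError("person count mismatch between data and abilities")
    if data.c != params.c:
        raise ValueError("category count mismatch")
    logp = log_softmax(category_logits(ability.theta, params), axis=-1)
    cell = np.take_along_axis(logp, data.scores[:, :, None], axis=-1)[:, :, 0]
    return float(cell[data.observed].sum())
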