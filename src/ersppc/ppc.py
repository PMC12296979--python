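"""Posterior predictive checks tailored to extreme response style (ERS).

Four checks are computed from observed data and posterior-replicated data:

Person level
    * ``PPP_ER^(n)`` — the proportion of replicated datasets in which person
      n's proportion of extreme responses (endpoint categories 1 or c)
      exceeds the observed proportion, counting exact ties as 1/2.  The
      check is two-sided: values below .05 flag a person as giving *more*
      extremes than the model expects (H-ERS), values above .95 as giving
      fewer (L-ERS).
    * ``PPP_D^(n)`` — a discrepancy check comparing squared differences
      between the extreme count and its model-expected value,
      ``D = (NE - E[NE])^2``, for replicated vs. observed data per draw.
      One-sided; values below .1 flag the person, with direction decided by
      whether the mean expected count sits below (H-ERS) or above (L-ERS)
      the observed count.

Group level
    * ``PPP_D`` — the same discrepancy summed over persons per draw.
    * ``PPP_ER`` — compares the across-person variance of extreme-response
      proportions, which individual ERS differences inflate even when the
      overall extreme rate is unchanged.  One-sided, tends to 0 under ERS;
      values below .1 indicate group-level ERS.

Tie handling in ``PPP_ER^(n)`` is exact by construction: because missing
cells are replicated in place, observed and replicated proportions share a
person's observed-item denominator, so equality is decided on integer
extreme counts, never on floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .gpcm import GpcmParameters, ResponseMatrix, category_logits
from .posterior import PosteriorDraws, _replicate_one

__all__ = [
    "PpcConfig",
    "PersonPpcResult",
    "GroupPpcResult",
    "extreme_proportion",
    "person_ppp_er",
    "expected_extreme_count",
    "person_ppp_d",
    "group_ppp_d",
    "group_ppp_er",
    "classify_flags",
    "run_ppc",
]

FLAG_NONE = "none"
FLAG_H = "H-ERS"
FLAG_L = "L-ERS"
FLAG_INDET = "indeterminate"


@dataclass
class PpcConfig:
    """Cutoffs and seeds for the checks (defaults as discussed above)."""

    er_lower: float = 0.05
    er_upper: float = 0.95
    d_cutoff: float = 0.1
    group_cutoff: float = 0.1
    seed: int = 0


@dataclass
class PersonPpcResult:
    """Per-person check outputs; arrays are aligned with ``person_ids``."""

    person_ids: list
    er_obs: np.ndarray
    ne_obs: np.ndarray
    n_observed: np.ndarray
    ppp_er: np.ndarray
    ppp_d: np.ndarray
    mean_expected_ne: np.ndarray
    flag_er: np.ndarray
    flag_d: np.ndarray
    direction_d: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "person": self.person_ids,
                "n_observed": self.n_observed,
                "er_obs": self.er_obs,
                "ne_obs": self.ne_obs,
                "ppp_er": self.ppp_er,
                "ppp_d": self.ppp_d,
                "mean_expected_ne": self.mean_expected_ne,
                "flag_er": self.flag_er,
                "flag_d": self.flag_d,
                "direction_d": self.direction_d,
            }
        )


@dataclass
class GroupPpcResult:
    ppp_er: float
    ppp_d: float
    n_draws: int
    flag_er: bool = False
    flag_d: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ppp_er": [self.ppp_er],
                "ppp_d": [self.ppp_d],
                "flag_er": [self.flag_er],
                "flag_d": [self.flag_d],
                "n_draws": [self.n_draws],
            }
        )


def extreme_proportion(responses: np.ndarray, c: int, missing_mask: np.ndarray | None = None) -> float:
    """Proportion of a person's observed responses in category 1 or c."""
    responses = np.asarray(responses)
    if missing_mask is None:
        missing_mask = np.zeros(responses.shape, dtype=bool)
    obs = ~np.asarray(missing_mask, dtype=bool)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("person has no observed responses")
    extreme = obs & ((responses == 1) | (responses == c))
    return float(extreme.sum()) / n_obs


def person_ppp_er(ne_obs: int, ne_rep: np.ndarray) -> float:
    """Two-sided person PPP on the extreme-response proportion.

    Because observed and replicated proportions share the denominator, the
    comparison is done on the integer extreme counts; ties contribute 1/2.
    """
    ne_rep = np.asarray(ne_rep)
    if ne_rep.size < 1:
        raise ValueError("need at least one replicated draw")
    gt = (ne_rep > ne_obs).mean()
    eq = (ne_rep == ne_obs).mean()
    return float(gt + 0.5 * eq)


def expected_extreme_count(
    theta_n: np.ndarray,
    params: GpcmParameters,
    observed_items: np.ndarray | None = None,
) -> float:
    """Model-expected number of extreme responses for one person at one draw.

    Sums P(bottom) + P(top) over the person's *observed* items so the
    expectation is commensurable with the observed count under missingness.
    """
    theta_n = np.atleast_1d(np.asarray(theta_n, dtype=float))
    probs = softmax(category_logits(theta_n[None, :], params), axis=-1)[0]
    p_ext = probs[:, 0] + probs[:, -1]
    if observed_items is not None:
        p_ext = p_ext[np.asarray(observed_items, dtype=bool)]
    return float(p_ext.sum())


def person_ppp_d(ne_obs: float, ne_rep: np.ndarray, expected: np.ndarray) -> float:
    """One-sided person PPP on the squared-discrepancy measure.

    ``expected`` is E[NE] per draw; ties count fully toward the numerator
    (the check is one-sided, so tied discrepancies are unproblematic).
    """
    ne_rep = np.asarray(ne_rep, dtype=float)
    expected = np.asarray(expected, dtype=float)
    d_obs = (ne_obs - expected) ** 2
    d_rep = (ne_rep - expected) ** 2
    return float((d_rep >= d_obs).mean())


def group_ppp_d(d_obs: np.ndarray, d_rep: np.ndarray) -> float:
    """Group discrepancy PPP: per-draw person-summed D_rep vs D_obs.

    Inputs are T x N matrices of per-draw, per-person discrepancies.
    """
    d_obs = np.atleast_2d(np.asarray(d_obs, dtype=float))
    d_rep = np.atleast_2d(np.asarray(d_rep, dtype=float))
    return float((d_rep.sum(axis=1) >= d_obs.sum(axis=1)).mean())


def _stable_variance(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Sample variance computed on sorted values.

    Sorting fixes the floating-point summation order, so the variance of a
    permutation of a vector is bit-identical to the original — the
    indicator comparisons in the group check never flip on rounding noise.
    """
    return np.sort(x, axis=axis).var(axis=axis, ddof=1)


def group_ppp_er(er_obs: np.ndarray, er_rep: np.ndarray) -> float:
    """Group ERS PPP on the across-person variance of extreme proportions.

    Sample variance (denominator N-1) on both sides; one replicated person
    vector per draw (T x N).
    """
    er_obs = np.asarray(er_obs, dtype=float)
    er_rep = np.atleast_2d(np.asarray(er_rep, dtype=float))
    v_obs = _stable_variance(er_obs)
    v_rep = _stable_variance(er_rep, axis=1)
    return float((v_rep >= v_obs).mean())


def classify_flags(
    ppp_er: np.ndarray,
    ppp_d: np.ndarray,
    ne_obs: np.ndarray,
    mean_expected_ne: np.ndarray,
    config: PpcConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag persons and attach ERS direction.

    ``PPP_ER`` below the lower cutoff means more observed extremes than
    replicated (H-ERS); above the upper cutoff, fewer (L-ERS).  A ``PPP_D``
    below its cutoff is directed by comparing the mean expected extreme
    count to the observed count; an exact tie is reported as indeterminate.
    """
    if config is None:
        config = PpcConfig()
    ppp_er = np.asarray(ppp_er, dtype=float)
    ppp_d = np.asarray(ppp_d, dtype=float)
    flag_er = np.full(ppp_er.shape, FLAG_NONE, dtype=object)
    flag_er[ppp_er < config.er_lower] = FLAG_H
    flag_er[ppp_er > config.er_upper] = FLAG_L
    flag_d = np.full(ppp_d.shape, FLAG_NONE, dtype=object)
    direction = np.full(ppp_d.shape, FLAG_NONE, dtype=object)
    flagged = ppp_d < config.d_cutoff
    higher = mean_expected_ne < ne_obs
    lower = mean_expected_ne > ne_obs
    direction[flagged & higher] = FLAG_H
    direction[flagged & lower] = FLAG_L
    tied = flagged & ~higher & ~lower
    if np.any(tied):
        warnings.warn(
            f"{int(tied.sum())} flagged person(s) with expected count exactly "
            "equal to observed; direction indeterminate"
        )
        direction[tied] = FLAG_INDET
    flag_d[flagged] = direction[flagged]
    return flag_er.astype(str), flag_d.astype(str), direction.astype(str)


def run_ppc(
    data: ResponseMatrix,
    draws: PosteriorDraws,
    config: PpcConfig | None = None,
) -> tuple[PersonPpcResult, GroupPpcResult]:
    """All four checks in one streamed pass over the posterior draws.

    Replicates are consumed draw by draw (never all materialized); the
    replicate random streams are the same ones :func:`replicate_datasets`
    produces for ``config.seed``, so a naive materialized computation gives
    byte-identical results.  Persons with no observed responses are
    excluded with a warning.
    """
    if config is None:
        config = PpcConfig()
    if data.n_persons != draws.theta.shape[1]:
        raise ValueError("draws person count does not match data")
    keep = data.observed.sum(axis=1) > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} person(s) with no observed responses"
        )
    idx = np.where(keep)[0]
    obs_mat = data.observed[idx]
    n_observed = obs_mat.sum(axis=1)
    ne_obs = data.is_extreme()[idx].sum(axis=1)
    er_obs = ne_obs / n_observed

    T = draws.n_draws
    n = idx.size
    count_gt = np.zeros(n)
    count_eq = np.zeros(n)
    count_d_ge = np.zeros(n)
    sum_expected = np.zeros(n)
    group_d_count = 0
    group_er_count = 0
    v_obs = _stable_variance(er_obs) if n > 1 else 0.0

    children = np.random.SeedSequence(config.seed).spawn(T)
    for t in range(T):
        rep = _replicate_one(draws, data, t, np.random.default_rng(children[t]))
        ne_rep = rep.is_extreme()[idx].sum(axis=1)
        expected = _expected_extreme_counts(draws, t, idx, obs_mat)
        count_gt += ne_rep > ne_obs
        count_eq += ne_rep == ne_obs
        d_obs = (ne_obs - expected) ** 2
        d_rep = (ne_rep - expected) ** 2
        count_d_ge += d_rep >= d_obs
        sum_expected += expected
        group_d_count += d_rep.sum() >= d_obs.sum()
        er_rep = ne_rep / n_observed
        v_rep = _stable_variance(er_rep) if n > 1 else 0.0
        group_er_count += v_rep >= v_obs

    ppp_er = (count_gt + 0.5 * count_eq) / T
    ppp_d = count_d_ge / T
    mean_expected = sum_expected / T
    flag_er, flag_d, direction = classify_flags(
        ppp_er, ppp_d, ne_obs, mean_expected, config
    )
    person = PersonPpcResult(
        person_ids=[data.person_ids[i] for i in idx],
        er_obs=er_obs,
        ne_obs=ne_obs,
        n_observed=n_observed,
        ppp_er=ppp_er,
        ppp_d=ppp_d,
        mean_expected_ne=mean_expected,
        flag_er=flag_er,
        flag_d=flag_d,
        direction_d=direction,
    )
    g_er = group_er_count / T
    g_d = group_d_count / T
    group = GroupPpcResult(
        ppp_er=float(g_er),
        ppp_d=float(g_d),
        n_draws=T,
        flag_er=bool(g_er < config.group_cutoff),
        flag_d=bool(g_d < config.group_cutoff),
    )
    return person, group


def _expected_extreme_counts(
    draws: PosteriorDraws, t: int, idx: np.ndarray, obs_mat: np.ndarray
) -> np.ndarray:
    """Vectorized E[NE] for the selected persons at draw t."""
    params = draws.params_at(t)
    logits = category_logits(draws.theta[t][idx], params)
    probs = softmax(logits, axis=-1)
    p_ext = probs[:, :, 0] + probs[:, :, -1]
    return (p_ext * obs_mat).sum(axis=1)
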