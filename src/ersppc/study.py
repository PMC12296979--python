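"""Simulation-study harness: false- and true-positive rates of the checks.

Each design cell (item count, dimension count, difficulty shift) is run for
a number of replications.  Every replication generates an IRTree dataset,
fits the GPCM by MCMC, runs all four posterior predictive checks and
records the flags.  Aggregation:

* group level — the proportion of replications whose group PPP fell below
  the cutoff (a false-positive rate under null data, a true-positive rate
  under experimental data);
* person level — the proportion of flagged persons among those whose true
  ERS value is zero (FPR), and, per nonzero ERS grid value, the proportion
  flagged among persons holding that value (TPR), pooled over replications.

Replication seeds are spawned from the master seed by a counter-based
scheme, so any subset of replications can be rerun independently and the
aggregate is invariant to execution order or worker count.  Non-converged
fits are kept but marked; aggregates excluding them are also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .irtree import ConditionSpec, generate_dataset
from .posterior import McmcConfig, sample_posterior
from .ppc import PpcConfig, run_ppc

__all__ = [
    "StudyResult",
    "ChiSquareResult",
    "run_condition",
    "tpr_by_ers",
    "covariate_association",
]

logger = logging.getLogger(__name__)


@dataclass
class ReplicationRecord:
    replication: int
    seed: int
    converged: bool
    max_rhat: float
    group_flag_er: bool
    group_flag_d: bool
    person_flag_er: np.ndarray  # bool per person
    person_flag_d: np.ndarray
    true_ers: np.ndarray


@dataclass
class StudyResult:
    """Aggregated outcomes of one design cell."""

    condition: ConditionSpec
    kind: str
    replications: int
    records: list = field(default_factory=list)

    def _person_pool(self, exclude_nonconverged: bool = False):
        recs = [
            r
            for r in self.records
            if r.converged or not exclude_nonconverged
        ]
        ers = np.concatenate([r.true_ers for r in recs])
        fe = np.concatenate([r.person_flag_er for r in recs])
        fd = np.concatenate([r.person_flag_d for r in recs])
        return ers, fe, fd

    def group_rates(self, exclude_nonconverged: bool = False) -> dict:
        recs = [
            r for r in self.records if r.converged or not exclude_nonconverged
        ]
        if not recs:
            return {"ppp_er": np.nan, "ppp_d": np.nan, "n": 0}
        return {
            "ppp_er": float(np.mean([r.group_flag_er for r in recs])),
            "ppp_d": float(np.mean([r.group_flag_d for r in recs])),
            "n": len(recs),
        }

    def person_fpr(self, exclude_nonconverged: bool = False) -> dict:
        """Flag rate among persons whose true ERS is zero."""
        ers, fe, fd = self._person_pool(exclude_nonconverged)
        null_mask = ers == 0.0
        n = int(null_mask.sum())
        if n == 0:
            return {"ppp_er": np.nan, "ppp_d": np.nan, "n": 0}
        return {
            "ppp_er": float(fe[null_mask].mean()),
            "ppp_d": float(fd[null_mask].mean()),
            "n": n,
        }

    def person_tpr(self, exclude_nonconverged: bool = False) -> pd.DataFrame:
        """TPR per nonzero true ERS grid value, pooled over replications."""
        ers, fe, fd = self._person_pool(exclude_nonconverged)
        rows = []
        for g in np.unique(ers):
            if g == 0.0:
                continue
            m = ers == g
            rows.append(
                {
                    "ers": float(g),
                    "tpr_ppp_er": float(fe[m].mean()) if m.any() else np.nan,
                    "tpr_ppp_d": float(fd[m].mean()) if m.any() else np.nan,
                    "n": int(m.sum()),
                }
            )
        return pd.DataFrame(rows)

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.records)


def _replication_seed(master_seed: int, cell_key: int, replication: int) -> int:
    """Counter-based seed derivation; independent of execution order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_key, replication))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def run_condition(
    spec: ConditionSpec,
    kind: str = "null",
    replications: int | None = None,
    master_seed: int = 0,
    mcmc_config: McmcConfig | None = None,
    ppc_config: PpcConfig | None = None,
    cell_key: int = 0,
    n_jobs: int = 1,
) -> StudyResult:
    """Run one design cell end to end (generate, fit, check, aggregate).

    Per-replication failures are logged and recorded as non-converged, never
    aborting the cell.  ``n_jobs > 1`` parallelizes over replications with
    joblib; results are identical for any worker count because every
    replication owns a derived seed.
    """
    if replications is None:
        replications = spec.replications
    if mcmc_config is None:
        mcmc_config = McmcConfig()
    if ppc_config is None:
        ppc_config = PpcConfig()

    def one(r: int) -> ReplicationRecord:
        seed = _replication_seed(master_seed, cell_key, r)
        return _run_replication(spec, kind, r, seed, mcmc_config, ppc_config)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(replications))
    else:
        records = [one(r) for r in range(replications)]
    return StudyResult(
        condition=spec, kind=kind, replications=replications, records=list(records)
    )


def _run_replication(
    spec: ConditionSpec,
    kind: str,
    r: int,
    seed: int,
    mcmc_config: McmcConfig,
    ppc_config: PpcConfig,
) -> ReplicationRecord:
    sim = generate_dataset(spec, kind, seed=seed)
    from dataclasses import replace

    cfg = replace(mcmc_config, seed=seed + 1)
    draws, report = sample_posterior(sim.responses, sim.dim_of_item, cfg)
    pcfg = PpcConfig(
        er_lower=ppc_config.er_lower,
        er_upper=ppc_config.er_upper,
        d_cutoff=ppc_config.d_cutoff,
        group_cutoff=ppc_config.group_cutoff,
        seed=seed + 2,
    )
    person, group = run_ppc(sim.responses, draws, pcfg)
    flag_er = person.flag_er != "none"
    flag_d = person.flag_d != "none"
    return ReplicationRecord(
        replication=r,
        seed=seed,
        converged=report.passed,
        max_rhat=report.max_rhat,
        group_flag_er=group.flag_er,
        group_flag_d=group.flag_d,
        person_flag_er=flag_er,
        person_flag_d=flag_d,
        true_ers=sim.ers,
    )


def tpr_by_ers(result: StudyResult) -> pd.DataFrame:
    """Per-ERS-value TPR table with a positive/negative asymmetry diagnostic."""
    table = result.person_tpr()
    if table.empty:
        return table
    rows = []
    for g in sorted(set(abs(table["ers"]))):
        pos = table[table["ers"] == g]
        neg = table[table["ers"] == -g]
        if len(pos) and len(neg):
            rows.append(
                {
                    "magnitude": g,
                    "asym_ppp_er": float(
                        neg["tpr_ppp_er"].iloc[0] - pos["tpr_ppp_er"].iloc[0]
                    ),
                    "asym_ppp_d": float(
                        neg["tpr_ppp_d"].iloc[0] - pos["tpr_ppp_d"].iloc[0]
                    ),
                }
            )
    asym = pd.DataFrame(rows)
    table.attrs["asymmetry"] = asym
    return table


@dataclass
class ChiSquareResult:
    table: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    small_cells: bool
    bonferroni_alpha: float


def covariate_association(
    flags: np.ndarray,
    covariate: np.ndarray,
    n_tests: int = 2,
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Pearson chi-square of the flag x covariate contingency table.

    ``flags`` take values in {L-ERS, none, H-ERS}; the covariate may have
    any number of levels L, giving df = 2(L-1).  The alpha is Bonferroni-
    adjusted over ``n_tests`` PPP families.  Expected counts below 5 are
    flagged, not rejected.
    """
    flags = np.asarray(flags)
    covariate = np.asarray(covariate)
    if flags.shape != covariate.shape:
        raise ValueError("flags and covariate must align")
    order = ["L-ERS", "none", "H-ERS"]
    tab = pd.crosstab(pd.Categorical(flags, categories=order), pd.Series(covariate))
    tab.index = order
    counts = tab.values
    keep_rows = counts.sum(axis=1) > 0
    counts = counts[keep_rows]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table needs at least two rows and columns")
    stat, p, df, expected = chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        table=tab,
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        expected=expected,
        small_cells=bool((expected < 5).any()),
        bonferroni_alpha=alpha / n_tests,
    )
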