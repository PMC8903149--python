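"""End-to-end orchestration of the four analytic steps.

1. descriptive screening,
2. group-specific one-factor fits with the adequacy gate (reported at both
   the exploratory and confirmatory stage; for one factor the two coincide
   structurally, so the same fit is screened twice),
3. the exact-invariance ladder on admitted groups,
4. alignment optimization with flagging, R-squared indices and the
   Monte-Carlo quality check — run regardless of whether exact invariance was
   attained, since approximate invariance is precisely the fallback for the
   usual case in which it is not,

followed by rankings on aligned factor means versus conventional prevalence,
CI-overlap clustering, a signed-rank concordance test, and convergent
correlations.  Factor-mean standard errors come from the Monte-Carlo
replications (parametric bootstrap), so rankings of aligned scores carry
uncertainty bands comparable to the prevalence side.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .alignment import (
    align,
    flag_invariance,
    invariance_r2,
    monte_carlo_quality,
)
from .binary_factor import adequacy_gate, fit_one_factor
from .comparison import (
    cluster_by_ci_overlap,
    convergent_correlations,
    rank_groups,
    wilcoxon_signed_rank,
)
from .descriptives import describe
from .exact_invariance import fit_multigroup, invariance_ladder
from .io_survey import ItemResponseTable, PipelineConfig

logger = logging.getLogger(__name__)


class GateFailure(RuntimeError):
    """Fewer than two groups passed the adequacy gate."""

    def __init__(self, message: str, gates):
        super().__init__(message)
        self.gates = gates


@dataclass
class StudyReport:
    """Structured output of one full run; serializable via write_report."""

    item_set: str
    config: PipelineConfig
    seed: int
    version: str
    descriptives: object
    group_fits: dict
    efa_gates: dict
    cfa_gates: dict
    admitted_groups: list
    ladder: object
    alignment: object
    monte_carlo: object
    trustworthy: bool
    ao_ranking: object
    prevalence_ranking: object
    rank_test: dict
    convergent: object


def run_full_study(table: ItemResponseTable, config: PipelineConfig | None = None) -> StudyReport:
    """Run the whole four-step analysis plus the ranking comparison."""
    config = config or PipelineConfig()
    table.require_multigroup()

    logger.info("step 1: descriptives on %d groups", table.n_groups)
    desc = describe(table)

    logger.info("step 2: group-specific one-factor fits and adequacy gate")
    fits, efa_gates, cfa_gates = {}, {}, {}
    for g in table.groups:
        fit = fits[g] = fit_one_factor(table, g)
        # one-factor exploratory and confirmatory stages share the solution;
        # the gate is echoed at both stages to mirror the sequential workflow
        efa_gates[g] = adequacy_gate(fit, config)
        cfa_gates[g] = efa_gates[g]
    admitted = [g for g in table.groups if cfa_gates[g].passed]
    logger.info("admitted %d/%d groups", len(admitted), table.n_groups)
    if len(admitted) < 2:
        raise GateFailure(
            f"only {len(admitted)} group(s) passed the adequacy gate", cfa_gates
        )
    sub = table.subset_groups(admitted)

    logger.info("step 3: exact-invariance ladder")
    ladder = invariance_ladder(sub, config)

    logger.info("step 4: alignment optimization")
    configural = fit_multigroup(
        sub, "configural", config, compute_se=True,
        warm_start=ladder.fits["configural"],
    )
    solution = align(configural, config)
    solution = flag_invariance(solution, configural, config.flag_alpha)
    invariance_r2(solution)
    trustworthy = (
        solution.pct_all is not None
        and solution.pct_all <= 100.0 * config.max_noninvariant_fraction
    )
    mc = None
    if config.mc_replications > 0:
        n_mc = int(np.median(solution.n_per_group))
        mc = monte_carlo_quality(
            solution, config.mc_replications, n_mc, seed=config.seed, config=config
        )
    if not trustworthy:
        logger.warning(
            "non-invariance share %.1f%% exceeds the trustworthiness limit; "
            "inspect the Monte-Carlo check before comparing factor means",
            solution.pct_all,
        )

    # downstream comparison
    labels = solution.group_labels
    if mc is not None and len(mc.estimated_means or []) >= 2:
        # centring each replicate on its panel mean measures every group's
        # uncertainty relative to the panel, so the reference group (whose
        # mean is 0 by convention) still carries a ranking SE
        boot = np.vstack(mc.estimated_means)
        boot = boot - boot.mean(axis=1, keepdims=True)
        ao_se = boot.std(axis=0, ddof=1)
    else:
        ao_se = np.full(len(labels), np.nan)
    ao_est = pd.DataFrame(
        {"estimate": solution.factor_means, "se": ao_se}, index=pd.Index(labels, name="group")
    )
    ao_rank = cluster_by_ci_overlap(rank_groups(ao_est, config.ci_level))
    prev_est = desc.any_prevalence.loc[admitted, ["estimate", "se"]]
    prev_rank = cluster_by_ci_overlap(rank_groups(prev_est, config.ci_level))

    common = ao_rank.table.index.intersection(prev_rank.table.index)
    stat, p = wilcoxon_signed_rank(
        ao_rank.table.loc[common, "rank"], prev_rank.table.loc[common, "rank"]
    )
    prev_cols = desc.item_prevalence.loc[admitted].copy()
    prev_cols["any"] = desc.any_prevalence.loc[admitted, "estimate"]
    convergent = convergent_correlations(
        pd.Series(solution.factor_means, index=labels), prev_cols
    )

    return StudyReport(
        item_set=table.item_set,
        config=config,
        seed=config.seed,
        version=_pkg_version,
        descriptives=desc,
        group_fits=fits,
        efa_gates=efa_gates,
        cfa_gates=cfa_gates,
        admitted_groups=admitted,
        ladder=ladder,
        alignment=solution,
        monte_carlo=mc,
        trustworthy=trustworthy,
        ao_ranking=ao_rank,
        prevalence_ranking=prev_rank,
        rank_test={"statistic": stat, "p_value": p},
        convergent=convergent,
    )
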