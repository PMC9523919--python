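"""Patient-level prognosis from CSL/CSV interactions.

Three stratifications: a single pair (target-low vs target-high among
partner-mutant patients), cumulative burden (none / fewer / more activated
pairs), and drug-target modules (partner unions sharing one target).  An
interaction is "activated" in a patient when the partner is mutated and the
target's expression lies on the configured side of the cohort-wide median
(default: below, mimicking drug inhibition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Cohort, InteractionType, ModuleDefinition
from .stats import KMCurve, TestResult, km_curve, logrank_test

log = logging.getLogger(__name__)

__all__ = [
    "ActivationRule",
    "SurvivalComparison",
    "single_pair_survival",
    "count_activated",
    "burden_groups",
    "build_module",
    "module_carrier_split",
    "compare_survival",
]


@dataclass(frozen=True)
class ActivationRule:
    """Pair activation: partner mutated AND target expression on one side of
    the cohort median ('low' by default) — or mutation alone if
    ``require_expression`` is off."""

    expression_side: str = "low"  # 'low' or 'high'
    require_expression: bool = True

    def __post_init__(self) -> None:
        if self.expression_side not in ("low", "high"):
            raise ValueError("expression_side must be 'low' or 'high'")


@dataclass
class SurvivalComparison:
    result: TestResult
    groups: dict  # label → (times, events)
    curves: dict  # label → KMCurve
    degenerate: bool = False
    reason: str = ""


def _surv_arrays(cohort: Cohort, samples) -> tuple[np.ndarray, np.ndarray]:
    surv = cohort.survival.loc[[s for s in samples if s in cohort.survival.index]]
    return surv["time"].to_numpy(float), surv["event"].to_numpy(float)


def compare_survival(groups: dict) -> SurvivalComparison:
    """Log-rank across named groups of (times, events); KM curve per group."""
    usable = {k: v for k, v in groups.items() if len(v[0]) > 0}
    if len(usable) < 2:
        raise ValueError("need at least two non-empty groups")
    res = logrank_test(list(usable.values()))
    curves = {k: km_curve(t, e) for k, (t, e) in usable.items()}
    return SurvivalComparison(result=res, groups=usable, curves=curves,
                              degenerate=res.degenerate)


def single_pair_survival(cohort: Cohort, interaction, min_mut_freq: float = 0.0):
    """Log-rank of target-low vs target-high among partner-mutant patients.

    The split is at the target's median expression within the mutant
    subcohort (ties low).  Returns a :class:`SurvivalComparison`, or a
    string reason when the subcohort is empty or single-sided.
    """
    from .cohort import GroupSplit, split_by_target_median

    split = split_by_target_median(cohort, interaction, min_mut_freq=min_mut_freq)
    if not isinstance(split, GroupSplit):
        return split.reason
    if split.degenerate or not split.low_group or not split.high_group:
        return "single-sided split at target median"
    groups = {
        "target_low": _surv_arrays(cohort, split.low_group),
        "target_high": _surv_arrays(cohort, split.high_group),
    }
    if any(len(t) == 0 for t, _ in groups.values()):
        return "no survival data on one side"
    return compare_survival(groups)


def count_activated(
    cohort: Cohort, interactions, rule: ActivationRule = ActivationRule()
) -> pd.Series:
    """Number of interactions activated per patient under ``rule``."""
    samples = list(cohort.samples)
    counts = pd.Series(0, index=samples, dtype=int)
    for ir in interactions:
        mut = cohort.mutations.altered_samples(ir.partner) & set(samples)
        if not mut:
            continue
        if not rule.require_expression:
            active = mut
        else:
            if ir.target not in cohort.expression.index:
                continue
            expr = cohort.expression.loc[ir.target]
            med = float(expr.median())
            if rule.expression_side == "low":
                side = set(expr.index[expr <= med])
            else:
                side = set(expr.index[expr > med])
            active = mut & side
        counts.loc[sorted(active)] += 1
    return counts


def burden_groups(counts: pd.Series) -> pd.Series:
    """Partition patients by activated-pair burden: none / fewer / more.

    Carriers (count > 0) are split at the median carrier count; ties at the
    median go to "fewer".  With no carriers everything is "none".
    """
    labels = pd.Series("none", index=counts.index, dtype=object)
    carriers = counts[counts > 0]
    if carriers.empty:
        log.warning("burden_groups: no carriers, single 'none' group")
        return labels
    med = float(carriers.median())
    labels[carriers.index[carriers <= med]] = "fewer"
    labels[carriers.index[carriers > med]] = "more"
    return labels


def build_module(interactions, target: str, tissue: str) -> ModuleDefinition:
    """Union of partners (and drugs) of one target in one tissue.

    All member interactions must share the interaction type; a CSL+CSV mix
    is a hard error.
    """
    members = [
        r for r in interactions
        if _ir(r).target == target and _ir(r).tissue == tissue
    ]
    if not members:
        raise ValueError(f"no interactions with target {target!r} in {tissue!r}")
    itypes = {_ir(r).itype for r in members}
    if len(itypes) > 1:
        raise ValueError(f"mixed interaction types for target {target!r}: "
                         f"{sorted(t.value for t in itypes)}")
    partners = frozenset(_ir(r).partner for r in members)
    drugs = frozenset(r.drug for r in members if hasattr(r, "drug"))
    return ModuleDefinition(target=target, tissue=tissue, partners=partners,
                            drugs=drugs, itype=itypes.pop())


def _ir(record):
    return record.interaction if hasattr(record, "interaction") else record


def module_carrier_split(
    cohort: Cohort, module: ModuleDefinition, rule: ActivationRule = ActivationRule()
) -> dict:
    """Patient groups for a drug-target module.

    CSV-style modules compare carriers of ≥1 activated module pair against
    all other patients.  CSL-style modules split the patients mutated in ≥1
    module partner by the target's median expression among them (target-low
    vs target-high).  Returns label → sample tuple; empty carrier sets are
    reported, not raised.
    """
    samples = list(cohort.samples)
    mutated = set()
    for p in module.partners:
        mutated |= cohort.mutations.altered_samples(p)
    mutated &= set(samples)
    if module.itype is InteractionType.CSV:
        if rule.require_expression and module.target in cohort.expression.index:
            expr = cohort.expression.loc[module.target]
            med = float(expr.median())
            if rule.expression_side == "low":
                side = set(expr.index[expr <= med])
            else:
                side = set(expr.index[expr > med])
            carriers = mutated & side
        else:
            carriers = mutated
        others = [s for s in samples if s not in carriers]
        if not carriers:
            log.warning("module %s: no carriers", module.target)
        return {"carrier": tuple(sorted(carriers)), "non_carrier": tuple(others)}
    # CSL-style: split module-mutant patients by target expression
    if module.target not in cohort.expression.index:
        raise ValueError(f"module target {module.target!r} not in expression")
    expr = cohort.expression.loc[module.target, sorted(mutated)].dropna()
    if expr.empty:
        log.warning("module %s: no mutant carriers with expression", module.target)
        return {"target_low": (), "target_high": ()}
    med = float(expr.median())
    return {
        "target_low": tuple(expr.index[expr <= med]),
        "target_high": tuple(expr.index[expr > med]),
    }


def survival_of_groups(cohort: Cohort, groups: dict) -> SurvivalComparison:
    """Convenience: map sample groups to (times, events) and compare."""
    arrs = {k: _surv_arrays(cohort, v) for k, v in groups.items() if len(v)}
    return compare_survival(arrs)
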