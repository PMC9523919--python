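"""Pharmacogenomic filtering: promote consensus interactions to drug biomarkers.

An interaction whose target is hit by a drug is retained when the drug
response (IC50/AUC, lower = more sensitive) of partner-mutant cell lines in
the interaction's tissue is shifted in the direction the interaction type
predicts: CSL → more sensitive, CSV → more resistant (one-sided rank-sum,
p < 0.05).  Each pharmacogenomic dataset is tested independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .datatypes import (
    Direction,
    DrugInteractionRecord,
    DrugResponseDataset,
    DrugTargetMap,
    InteractionRecord,
    InteractionType,
    MutationCatalog,
)
from .screens import DEFAULT_MIN_GROUP, DEFAULT_MIN_TISSUE_LINES
from .stats import Alternative, rank_sum_test

log = logging.getLogger(__name__)

__all__ = [
    "Rejection",
    "map_interactions_to_drugs",
    "drug_response_test",
    "aggregate_drug_evidence",
]


@dataclass(frozen=True)
class Rejection:
    """A (interaction, drug, dataset) combination that did not pass, with why."""

    interaction: InteractionRecord
    drug: str
    pharmaco_dataset: str
    reason: str
    p: float | None = None


def map_interactions_to_drugs(interactions, targets: DrugTargetMap):
    """Pair each interaction with every drug whose target set contains its target."""
    pairs = []
    for ir in interactions:
        for drug in targets.drugs_for_target(ir.target):
            pairs.append((ir, drug))
    return pairs


def drug_response_test(
    pair,
    dataset: DrugResponseDataset,
    mutations: MutationCatalog,
    min_group: int = DEFAULT_MIN_GROUP,
    min_tissue_lines: int = DEFAULT_MIN_TISSUE_LINES,
    alpha: float = 0.05,
):
    """Test one (interaction, drug) pair in one pharmacogenomic dataset.

    Returns a :class:`DrugInteractionRecord` when the partner-mutant shift
    matches the interaction type at ``alpha``, otherwise a :class:`Rejection`
    naming the reason (drug unmeasured, tissue too small, wrong direction…).
    """
    interaction, drug = pair
    if drug not in dataset.responses.index:
        return Rejection(interaction, drug, dataset.name, "drug not measured")
    tissue = interaction.tissue
    in_tissue = [
        c for c in dataset.responses.columns
        if dataset.lineages.get(c) == tissue
    ]
    responses = dataset.responses.loc[drug, in_tissue].dropna()
    if len(responses) < min_tissue_lines:
        return Rejection(interaction, drug, dataset.name, "tissue too small")
    mut_samples = mutations.altered_samples(interaction.partner)
    is_mut = responses.index.isin(mut_samples)
    mut = responses.to_numpy()[is_mut]
    wt = responses.to_numpy()[~is_mut]
    if len(mut) < min_group or len(wt) < min_group:
        return Rejection(interaction, drug, dataset.name, "group too small")
    if interaction.itype is InteractionType.CSL:
        alt, direction = Alternative.LESS, Direction.SENSITIVE
    else:
        alt, direction = Alternative.GREATER, Direction.RESISTANT
    res = rank_sum_test(mut, wt, alt)
    if res.p_value >= alpha:
        return Rejection(
            interaction, drug, dataset.name, "not significant", p=res.p_value
        )
    return DrugInteractionRecord(
        interaction=interaction,
        drug=drug,
        pharmaco_dataset=dataset.name,
        drug_p=res.p_value,
        direction=direction,
        n_mut=len(mut),
        n_wt=len(wt),
    )


def aggregate_drug_evidence(records) -> pd.DataFrame:
    """One summary row per (target, partner, tissue, itype, drug) with its
    supporting pharmacogenomic datasets and p-values."""
    rows = [
        {
            "target": r.interaction.target,
            "partner": r.interaction.partner,
            "tissue": r.interaction.tissue,
            "itype": r.interaction.itype.value,
            "drug": r.drug,
            "pharmaco_dataset": r.pharmaco_dataset,
            "drug_p": r.drug_p,
        }
        for r in records
    ]
    cols = ["target", "partner", "tissue", "itype", "drug", "pharmaco_dataset", "drug_p"]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return pd.DataFrame(
            columns=["target", "partner", "tissue", "itype", "drug",
                     "n_datasets", "datasets", "p_values"]
        )
    out = (
        df.groupby(["target", "partner", "tissue", "itype", "drug"], sort=True)
        .agg(
            n_datasets=("pharmaco_dataset", "nunique"),
            datasets=("pharmaco_dataset", lambda s: ",".join(sorted(s))),
            p_values=("drug_p", lambda s: ",".join(repr(v) for v in s)),
        )
        .reset_index()
    )
    return out
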