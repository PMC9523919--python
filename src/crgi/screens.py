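"""Candidate CSL/CSV discovery from perturbation screens and multi-screen consensus.

Per tissue, the viability of target knockout is compared between cell lines
with and without partner alteration (one-sided rank-sum both ways).  Pairs
nominally significant in the same direction in at least two screens are
Fisher-combined across every screen where they were testable; a combined
p < 0.05 yields a consensus interaction.  Pairs significant as lethal in one
screen and viable in another are emitted as conflict records, never as
consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    InteractionRecord,
    InteractionType,
    MutationCatalog,
    Orientation,
    ScreenDataset,
)
from .stats import Alternative, fisher_combine, rank_sum_test

log = logging.getLogger(__name__)

__all__ = [
    "PairTest",
    "orient_to_viability",
    "eligible_tissues",
    "test_pair",
    "scan_candidates",
    "consensus",
    "DEFAULT_MIN_TISSUE_LINES",
    "DEFAULT_MIN_GROUP",
]

#: "more than three cell lines" per tissue
DEFAULT_MIN_TISSUE_LINES = 4
#: minimum mutant and wild-type group size per pair test
DEFAULT_MIN_GROUP = 3


@dataclass(frozen=True)
class PairTest:
    """One (target, partner) rank-sum test in one tissue of one screen."""

    target: str
    partner: str
    tissue: str
    screen: str
    p_lethal: float  # alternative: mutant viability lower
    p_viable: float  # alternative: mutant viability higher
    n_mut: int
    n_wt: int
    tested: bool = True
    reason: str = ""


def orient_to_viability(screen: ScreenDataset) -> ScreenDataset:
    """Return the screen with scores satisfying "higher = more viable".

    LOW_IS_VIABLE scores are negated and the flag flipped; the operation is
    idempotent on HIGH_IS_VIABLE screens.
    """
    if screen.orientation is Orientation.HIGH_IS_VIABLE:
        return screen
    return ScreenDataset(
        name=screen.name,
        orientation=Orientation.HIGH_IS_VIABLE,
        scores=-screen.scores,
        lineages=screen.lineages,
    )


def eligible_tissues(screen: ScreenDataset, min_lines: int = DEFAULT_MIN_TISSUE_LINES):
    """Tissues with at least ``min_lines`` cell lines in the screen."""
    counts = screen.lineages.loc[
        screen.lineages.index.isin(screen.scores.columns)
    ].value_counts()
    return sorted(counts[counts >= min_lines].index)


def _split_scores(
    scores: pd.Series, mutant_samples: set
) -> tuple[np.ndarray, np.ndarray]:
    scores = scores.dropna()
    is_mut = scores.index.isin(mutant_samples)
    return scores.to_numpy()[is_mut], scores.to_numpy()[~is_mut]


def test_pair(
    screen: ScreenDataset,
    mutations: MutationCatalog,
    tissue: str,
    target: str,
    partner: str,
    min_group: int = DEFAULT_MIN_GROUP,
) -> PairTest:
    """Rank-sum test of target-knockout viability split by partner alteration.

    The screen must already be oriented to viability.  Groups below
    ``min_group`` yield an untested record (not p = 1).
    """
    if screen.orientation is not Orientation.HIGH_IS_VIABLE:
        raise ValueError("screen must be oriented to viability first")
    if target not in screen.scores.index:
        return PairTest(target, partner, tissue, screen.name, 1.0, 1.0, 0, 0,
                        tested=False, reason="target absent from screen")
    lines = screen.tissue_lines(tissue)
    mut, wt = _split_scores(
        screen.scores.loc[target, lines], mutations.altered_samples(partner)
    )
    if len(mut) < min_group or len(wt) < min_group:
        return PairTest(target, partner, tissue, screen.name, 1.0, 1.0,
                        len(mut), len(wt), tested=False, reason="group too small")
    res_l = rank_sum_test(mut, wt, Alternative.LESS)
    res_v = rank_sum_test(mut, wt, Alternative.GREATER)
    return PairTest(
        target, partner, tissue, screen.name,
        p_lethal=res_l.p_value, p_viable=res_v.p_value,
        n_mut=len(mut), n_wt=len(wt),
    )


def scan_candidates(
    screens,
    mutation_catalogs,
    cr_genes,
    targets,
    partners=None,
    pairs=None,
    alpha: float = 0.05,
    min_lines: int = DEFAULT_MIN_TISSUE_LINES,
    min_group: int = DEFAULT_MIN_GROUP,
) -> pd.DataFrame:
    """Test CR-containing (target, partner) pairs in every eligible tissue.

    Parameters
    ----------
    screens : list of ScreenDataset (any orientation; normalised internally)
    mutation_catalogs : dict screen-name → MutationCatalog
    cr_genes : chromatin-regulator gene set; a pair is tested only if at
        least one side is a CR
    targets : genes considered as knockout targets
    partners : mutated genes considered as partners (default: all altering
        genes of each screen's catalog)
    pairs : optional explicit list of (target, partner) hypotheses; when
        given, only these combinations are tested (the designed-pair mode
        used by simulation studies), otherwise the full target × partner
        cross is scanned
    alpha : nominal one-sided significance level (default 0.05)

    Returns
    -------
    DataFrame with one row per tested (screen, tissue, target, partner),
    including non-significant rows (the consensus step combines p-values
    over every screen where a pair was testable).  Columns ``sig_lethal`` /
    ``sig_viable`` mark nominal significance at ``alpha``.
    """
    cr_genes = set(cr_genes)
    targets = sorted(targets)
    pair_map = None
    if pairs is not None:
        pair_map = {}
        for t, p in pairs:
            pair_map.setdefault(t, []).append(p)
        targets = sorted(set(pair_map) & set(targets))
    rows = []
    for screen in screens:
        oriented = orient_to_viability(screen)
        catalog = mutation_catalogs[screen.name]
        screen_partners = sorted(partners) if partners is not None else catalog.genes
        tissues = eligible_tissues(oriented, min_lines=min_lines)
        if not tissues:
            log.warning("screen %s: no tissue with >= %d lines", screen.name, min_lines)
            continue
        # per-partner mutant sets are reused across targets
        all_partners = (
            screen_partners if pair_map is None
            else sorted({p for ps in pair_map.values() for p in ps})
        )
        mut_sets = {p: catalog.altered_samples(p) for p in all_partners}
        for tissue in tissues:
            lines = oriented.tissue_lines(tissue)
            sub = oriented.scores[lines]
            for target in targets:
                if target not in sub.index:
                    continue
                tscores = sub.loc[target].dropna()
                t_partners = (
                    screen_partners if pair_map is None else sorted(pair_map[target])
                )
                for partner in t_partners:
                    if partner == target:
                        continue
                    if target not in cr_genes and partner not in cr_genes:
                        continue
                    is_mut = tscores.index.isin(mut_sets[partner])
                    mut = tscores.to_numpy()[is_mut]
                    wt = tscores.to_numpy()[~is_mut]
                    if len(mut) < min_group or len(wt) < min_group:
                        continue
                    res_l = rank_sum_test(mut, wt, Alternative.LESS)
                    res_v = rank_sum_test(mut, wt, Alternative.GREATER)
                    rows.append(
                        {
                            "screen": screen.name,
                            "tissue": tissue,
                            "target": target,
                            "partner": partner,
                            "p_lethal": res_l.p_value,
                            "p_viable": res_v.p_value,
                            "n_mut": len(mut),
                            "n_wt": len(wt),
                            "sig_lethal": res_l.p_value < alpha,
                            "sig_viable": res_v.p_value < alpha,
                        }
                    )
    cols = [
        "screen", "tissue", "target", "partner", "p_lethal", "p_viable",
        "n_mut", "n_wt", "sig_lethal", "sig_viable",
    ]
    df = pd.DataFrame(rows, columns=cols)
    log.info(
        "scan: %d tests, %d lethal-significant, %d viable-significant",
        len(df), int(df["sig_lethal"].sum()) if len(df) else 0,
        int(df["sig_viable"].sum()) if len(df) else 0,
    )
    return df


def consensus(
    pair_tests: pd.DataFrame,
    min_support: int = 2,
    alpha_combined: float = 0.05,
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Build the multi-screen consensus from the full scan table.

    For each (target, partner, tissue) significant in the same direction in
    at least ``min_support`` screens, the directional p-values from *all*
    screens where the pair was tested are Fisher-combined; records are kept
    when the combined p < ``alpha_combined``.  Pairs significant as CSL in
    one screen and CSV in another become conflict records (returned
    separately, flagged, itype per direction).

    Returns ``(consensus_records, conflict_records)``.
    """
    records: list[InteractionRecord] = []
    conflicts: list[InteractionRecord] = []
    if pair_tests.empty:
        return records, conflicts
    for (target, partner, tissue), grp in pair_tests.groupby(
        ["target", "partner", "tissue"], sort=True
    ):
        support_l = frozenset(grp.loc[grp["sig_lethal"], "screen"])
        support_v = frozenset(grp.loc[grp["sig_viable"], "screen"])
        n_mut = int(grp["n_mut"].max())
        n_wt = int(grp["n_wt"].max())

        def _make(itype, pcol, support, conflict=False):
            per_p = dict(zip(grp["screen"], grp[pcol]))
            return InteractionRecord(
                target=target, partner=partner, tissue=tissue, itype=itype,
                per_dataset_p=per_p, n_mut=n_mut, n_wt=n_wt,
                combined_p=fisher_combine(list(per_p.values())),
                support=support, conflict=conflict,
            )

        if support_l and support_v:
            conflicts.append(_make(InteractionType.CSL, "p_lethal", support_l, True))
            conflicts.append(_make(InteractionType.CSV, "p_viable", support_v, True))
            continue
        if len(support_l) >= min_support:
            rec = _make(InteractionType.CSL, "p_lethal", support_l)
            if rec.combined_p < alpha_combined:
                records.append(rec)
        elif len(support_v) >= min_support:
            rec = _make(InteractionType.CSV, "p_viable", support_v)
            if rec.combined_p < alpha_combined:
                records.append(rec)
    log.info("consensus: %d records, %d conflict pairs", len(records), len(conflicts) // 2)
    return records, conflicts
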