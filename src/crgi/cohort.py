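"""Patient-cohort validation of CSL/CSV interactions.

Within partner-mutant patients, target expression below the median mimics
drug inhibition of the target; the target-low group is therefore the
reference everywhere: "up" means higher in target-low patients.  Validation
covers pairwise correlation structure, directional differential omics
(expression, methylation, accessibility — one generic operation), shifts in
per-sample scores (HRD, immune fractions), and pathway enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Cohort, InteractionRecord, PathwayCollection
from .stats import (
    Alternative,
    TestResult,
    bh_adjust,
    hypergeom_tail,
    pearson,
    rank_sum_test,
)

log = logging.getLogger(__name__)

__all__ = [
    "GroupSplit",
    "SkipReason",
    "pairwise_correlation",
    "split_by_target_median",
    "differential_features",
    "score_shift_test",
    "pathway_enrichment",
    "DEFAULT_MIN_MUT_FREQ",
    "DEFAULT_FDR",
]

#: partner "mutation frequency more than 10%" inclusion rule
DEFAULT_MIN_MUT_FREQ = 0.10
DEFAULT_FDR = 0.1


@dataclass(frozen=True)
class GroupSplit:
    """Partner-mutant samples split at the target's median expression.

    Ties at the median go to ``low_group``; low/high are disjoint and their
    union is the partner-mutant samples with expression data.
    """

    target: str
    partner: str
    low_group: tuple
    high_group: tuple
    degenerate: bool = False


@dataclass(frozen=True)
class SkipReason:
    target: str
    partner: str
    reason: str


def pairwise_correlation(
    matrix: pd.DataFrame, pairs, kind: str = "expression", alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation per (target, partner) pair across samples.

    Class is "positive"/"negative" when significant at ``alpha``, else
    "none"; unmeasured genes or zero-variance profiles yield a "skipped"
    row with the reason.
    """
    rows = []
    for target, partner in pairs:
        row = {"target": target, "partner": partner, "kind": kind}
        if target not in matrix.index or partner not in matrix.index:
            row.update(r=np.nan, p=np.nan, cls="skipped", reason="gene unmeasured")
        else:
            x = matrix.loc[target].astype(float)
            y = matrix.loc[partner].astype(float)
            ok = x.notna() & y.notna()
            try:
                r, p = pearson(x[ok], y[ok])
            except ValueError as exc:
                row.update(r=np.nan, p=np.nan, cls="skipped", reason=str(exc))
            else:
                cls = "none"
                if p < alpha:
                    cls = "positive" if r > 0 else "negative"
                row.update(r=r, p=p, cls=cls, reason="")
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["target", "partner", "kind", "r", "p", "cls", "reason"]
    )


def split_by_target_median(
    cohort: Cohort,
    interaction: InteractionRecord,
    min_mut_freq: float = DEFAULT_MIN_MUT_FREQ,
):
    """Split partner-mutant patients at the target's median expression.

    Requires partner mutation frequency in the cohort strictly above
    ``min_mut_freq``; expression ≤ median goes to the low group.  Returns a
    :class:`GroupSplit` or a :class:`SkipReason`.
    """
    target, partner = interaction.target, interaction.partner
    samples = list(cohort.samples)
    mut = cohort.mutations.altered_samples(partner) & set(samples)
    freq = len(mut) / len(samples) if samples else 0.0
    if freq <= min_mut_freq:
        return SkipReason(target, partner,
                          f"partner mutation frequency {freq:.3f} <= {min_mut_freq}")
    if target not in cohort.expression.index:
        return SkipReason(target, partner, "target not in expression matrix")
    expr = cohort.expression.loc[target, sorted(mut)].dropna()
    if expr.empty:
        return SkipReason(target, partner, "no expression in mutant samples")
    med = float(expr.median())
    low = tuple(expr.index[expr <= med])
    high = tuple(expr.index[expr > med])
    return GroupSplit(target, partner, low, high, degenerate=len(high) == 0)


def differential_features(
    matrix: pd.DataFrame, split: GroupSplit, fdr: float = DEFAULT_FDR
) -> tuple[set, set]:
    """Directional differential features between the split's two groups.

    Per feature, one-sided rank-sum tests in both directions (up = higher in
    the low/reference group), BH across features separately per direction;
    features with adjusted p < ``fdr`` are returned as (up, down).  A
    feature passing both directions (possible only at very large ``fdr``)
    is assigned to its smaller raw p so the two sets stay disjoint.
    """
    low = [s for s in split.low_group if s in matrix.columns]
    high = [s for s in split.high_group if s in matrix.columns]
    if len(low) < 3 or len(high) < 3:
        raise ValueError(f"group too small for differential testing "
                         f"({len(low)} low / {len(high)} high)")
    feats, p_up, p_down = [], [], []
    lo = matrix[low]
    hi = matrix[high]
    for feat in matrix.index:
        x = lo.loc[feat].dropna().to_numpy()
        y = hi.loc[feat].dropna().to_numpy()
        if len(x) < 3 or len(y) < 3:
            continue
        feats.append(feat)
        p_up.append(rank_sum_test(x, y, Alternative.GREATER).p_value)
        p_down.append(rank_sum_test(x, y, Alternative.LESS).p_value)
    if not feats:
        return set(), set()
    adj_up = bh_adjust(p_up)
    adj_down = bh_adjust(p_down)
    up, down = set(), set()
    for f, pu, pd_, au, ad in zip(feats, p_up, p_down, adj_up, adj_down):
        sig_u, sig_d = au < fdr, ad < fdr
        if sig_u and sig_d:  # degenerate large-fdr case: keep one direction
            (up if pu <= pd_ else down).add(f)
        elif sig_u:
            up.add(f)
        elif sig_d:
            down.add(f)
    return up, down


def score_shift_test(
    sample_scores: pd.Series, split: GroupSplit, alpha: float = 0.05
) -> dict:
    """One-sided score shift between groups, reporting the stronger direction.

    "up" means the score is higher in the low (reference) group.  Returns a
    dict with direction, the directional :class:`TestResult`, and a
    ``significant`` flag at ``alpha``.
    """
    x = sample_scores.reindex(list(split.low_group)).dropna().to_numpy()
    y = sample_scores.reindex(list(split.high_group)).dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        return {"direction": None, "result": None, "significant": False,
                "reason": "score missing in a group"}
    res_up = rank_sum_test(x, y, Alternative.GREATER)
    res_down = rank_sum_test(x, y, Alternative.LESS)
    if res_up.p_value <= res_down.p_value:
        direction, res = "up", res_up
    else:
        direction, res = "down", res_down
    return {
        "direction": direction,
        "result": res,
        "significant": (res.p_value < alpha) and not res.degenerate,
        "reason": "",
    }


def pathway_enrichment(
    genes, pathways: PathwayCollection, universe, fdr: float = DEFAULT_FDR
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set in each pathway.

    Pathways are intersected with the universe; BH across pathways; the
    ``significant`` column marks adjusted p < ``fdr``.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway collection")
    genes, universe = set(genes), set(universe)
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name in sorted(pathways.sets):
        members = pathways.sets[name] & universe
        if not members:
            continue
        k = len(genes & members)
        p = hypergeom_tail(k, len(members), len(genes), len(universe))
        rows.append({"pathway": name, "overlap": k, "size": len(members), "p": p})
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "size", "p"])
    if df.empty:
        df["adjusted_p"] = []
        df["significant"] = []
        return df
    df["adjusted_p"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["adjusted_p"] < fdr
    return df.sort_values(["adjusted_p", "p", "pathway"]).reset_index(drop=True)
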