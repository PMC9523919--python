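"""Drug-pair similarity by shared interaction partners and therapeutic codes.

Two drugs are called "similar" when their partner-gene sets overlap more
than expected under a hypergeometric draw from the network's partner
universe.  Agreement with the clinic is scored by the Jaccard similarity of
ATC codes (or externally supplied GO semantic similarity) compared between
similar and non-similar pairs with a Welch t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .datatypes import AtcCatalog
from .stats import TestResult, hypergeom_tail, two_sample_t

__all__ = [
    "SharedPartnerResult",
    "shared_partner_test",
    "atc_jaccard",
    "compare_groups",
    "drug_pair_table",
]


@dataclass(frozen=True)
class SharedPartnerResult:
    overlap: int
    p: float
    similar: bool


def shared_partner_test(
    partners_a, partners_b, universe, alpha: float = 0.05
) -> SharedPartnerResult:
    """Hypergeometric overlap test of two drugs' partner-gene sets.

    p = P(X ≥ |A∩B|) drawing |B| genes from the universe with |A| marked.
    Symmetric in the two drugs.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty partner universe")
    a, b = set(partners_a), set(partners_b)
    if not a <= universe or not b <= universe:
        raise ValueError("partner sets must be subsets of the universe")
    k = len(a & b)
    p = hypergeom_tail(k, len(a), len(b), len(universe))
    return SharedPartnerResult(overlap=k, p=p, similar=p < alpha)


def atc_jaccard(codes_a, codes_b) -> float:
    """Jaccard similarity |∩|/|∪| of two non-empty ATC code sets."""
    a, b = set(codes_a), set(codes_b)
    if not a or not b:
        raise ValueError("ATC code set is empty: similarity undefined")
    return len(a & b) / len(a | b)


def compare_groups(similar_scores, other_scores) -> TestResult:
    """Welch t test of similarity scores, similar pairs vs other pairs."""
    return two_sample_t(similar_scores, other_scores)


def drug_pair_table(
    drug_partners: dict,
    atc: AtcCatalog | None = None,
    universe=None,
    alpha: float = 0.05,
    atc_prefix: int | None = None,
) -> pd.DataFrame:
    """All-pairs similarity table over a drug → partner-set map.

    ``universe`` defaults to the union of all partner sets (the partners
    appearing in the relevant network).  ``atc_prefix`` optionally truncates
    ATC codes to their first N characters before the Jaccard computation;
    drugs without ATC codes get a missing jaccard value, not zero.
    """
    if universe is None:
        universe = set().union(*drug_partners.values()) if drug_partners else set()
    rows = []
    for da, db in combinations(sorted(drug_partners), 2):
        res = shared_partner_test(drug_partners[da], drug_partners[db], universe, alpha)
        jac = None
        if atc is not None:
            ca, cb = atc.codes.get(da, set()), atc.codes.get(db, set())
            if atc_prefix is not None:
                ca = {c[:atc_prefix] for c in ca}
                cb = {c[:atc_prefix] for c in cb}
            if ca and cb:
                jac = atc_jaccard(ca, cb)
        rows.append(
            {
                "drug_a": da,
                "drug_b": db,
                "overlap": res.overlap,
                "p": res.p,
                "similar": res.similar,
                "atc_jaccard": jac,
            }
        )
    return pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "overlap", "p", "similar", "atc_jaccard"]
    )
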