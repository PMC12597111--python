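"""Founder pedigrees, non-overlapping case clusters, and the per-pedigree
Poisson excess test that defines high-risk families.

A founder pedigree is the full descendant set of a genealogy founder (an
individual with no recorded parents).  Founder pedigrees may overlap — a
case can descend from many founders — while :func:`nonoverlapping_clusters`
partitions the case set into connected components of the case-relatedness
graph (two cases linked iff their kinship is positive, i.e. they share a
recorded ancestor).  Each pedigree's observed case count is compared with
the sum of cohort-specific rates over its descendants via the one-tailed
Poisson test; no multiplicity correction is applied by design, which
prioritises sensitivity and is conservative per-pedigree for discrete
counts.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Set

from .pedigree import Genealogy
from .kinship import _ancestor_depths
from .risk import RateTable, poisson_upper_p

__all__ = [
    "FounderPedigree",
    "HighRiskCall",
    "founder_pedigrees",
    "nonoverlapping_clusters",
    "pedigree_excess_test",
    "high_risk_scan",
]


@dataclass(frozen=True)
class FounderPedigree:
    """All descendants of one founder, with its case excess statistics."""

    founder_id: str
    descendants: FrozenSet[str]
    case_descendants: FrozenSet[str]
    observed: int
    expected: Optional[float] = None
    p: Optional[float] = None


@dataclass(frozen=True)
class HighRiskCall:
    pedigree: FounderPedigree
    high_risk: bool
    alpha: float


def _descendants(g: Genealogy, founder: str) -> Set[str]:
    cm = g.children_map()
    seen: Set[str] = set()
    stack = list(cm[founder])
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(cm[cur])
    return seen


def founder_pedigrees(
    g: Genealogy, cases: Iterable[str], min_cases: int = 2
) -> List[FounderPedigree]:
    """One pedigree per founder whose descendants include >= min_cases cases.

    Output may overlap (e.g. the two members of a founder couple yield
    pedigrees with identical descendant sets); ordered by founder id.
    """
    if min_cases < 2:
        raise ValueError("min_cases must be >= 2")
    case_set = set(cases)
    out: List[FounderPedigree] = []
    for founder in sorted(g.founders()):
        desc = _descendants(g, founder)
        case_desc = desc & case_set
        if len(case_desc) >= min_cases:
            out.append(
                FounderPedigree(
                    founder_id=founder,
                    descendants=frozenset(desc),
                    case_descendants=frozenset(case_desc),
                    observed=len(case_desc),
                )
            )
    return out


def nonoverlapping_clusters(g: Genealogy, cases: Iterable[str]) -> List[Set[str]]:
    """Partition the cases into maximal groups of mutually traceable kin.

    Two cases fall in the same cluster iff they are connected in the graph
    whose edges join case pairs with positive kinship (equivalently: pairs
    sharing a recorded common ancestor, one possibly ancestral to the
    other).  Singletons form their own clusters.  Ordered largest first.
    """
    case_list = sorted(set(cases))
    parent: Dict[str, str] = {c: c for c in case_list}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    owner: Dict[str, str] = {}
    for case in case_list:
        for anc in _ancestor_depths(g, case):  # includes the case itself
            if anc in owner:
                union(case, owner[anc])
            else:
                owner[anc] = case
    groups: Dict[str, Set[str]] = {}
    for case in case_list:
        groups.setdefault(find(case), set()).add(case)
    return sorted(groups.values(), key=lambda s: (-len(s), min(s)))


def pedigree_excess_test(g: Genealogy, ped: FounderPedigree, rates: RateTable) -> FounderPedigree:
    """Fill in expected count and one-tailed Poisson p for a founder pedigree.

    expected = sum of cohort rates over all descendants.  When expected is 0
    with observed > 0 (rates unavailable for every descendant cohort) the
    result is degenerate: p is reported as the smallest positive float with
    a warning rather than an error.
    """
    expected = sum(rates.rate_for(g[d]) for d in ped.descendants)
    if expected > 0:
        p = poisson_upper_p(ped.observed, expected)
    elif ped.observed == 0:
        p = 1.0
    else:
        warnings.warn(
            f"pedigree {ped.founder_id!r}: observed {ped.observed} cases with zero "
            "expected count; p degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        p = sys.float_info.min
    return replace(ped, expected=expected, p=p)


def high_risk_scan(
    g: Genealogy,
    cases: Iterable[str],
    rates: RateTable,
    alpha: float = 0.05,
    min_cases: int = 2,
) -> List[HighRiskCall]:
    """Test every founder pedigree for case excess; call high risk at p < alpha.

    Founder couples (identical descendant sets) are reported once, labelled
    by the earlier-born founder.  A pedigree is high risk iff p < alpha and
    observed >= 2.  No multiple-testing adjustment; sorted by p ascending.
    """
    peds = founder_pedigrees(g, cases, min_cases=min_cases)
    by_desc: Dict[FrozenSet[str], FounderPedigree] = {}
    for ped in peds:
        prev = by_desc.get(ped.descendants)
        if prev is None or (
            g[ped.founder_id].birth_year,
            ped.founder_id,
        ) < (g[prev.founder_id].birth_year, prev.founder_id):
            by_desc[ped.descendants] = ped
    calls = [
        HighRiskCall(
            pedigree=(tested := pedigree_excess_test(g, ped, rates)),
            high_risk=tested.p < alpha and tested.observed >= 2,
            alpha=alpha,
        )
        for ped in by_desc.values()
    ]
    return sorted(calls, key=lambda c: (c.pedigree.p, c.pedigree.founder_id))
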