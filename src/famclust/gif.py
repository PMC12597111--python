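"""Genealogical Index of Familiality: case statistic, matched-control null,
empirical significance, and the per-genetic-distance decomposition.

The GIF is the mean pairwise Malécot kinship over all unordered case pairs,
scaled by 1e5 (the convention used in Utah Population Database studies, so
that typical values land in the units range).  Significance is empirical:
the case GIF is compared with the GIF of control sets matched per-case on
sex, birth year (within a window), birth place and genealogical
informativeness.  The distant GIF (dGIF) zeroes the contribution of pairs
closer than a meiotic-distance cutoff while keeping the pair count in the
denominator, isolating aggregation beyond the nuclear family on the same
scale as the GIF.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .pedigree import Genealogy, generation_depth
from .kinship import genetic_distance, kinship_matrix

__all__ = [
    "GIF_SCALE",
    "MatchingSpec",
    "MatchingError",
    "GIFResult",
    "gif_statistic",
    "dgif_statistic",
    "distance_contributions",
    "sample_matched_controls",
    "gif_test",
]

#: scaling constant applied to mean pairwise kinship (UPDB convention)
GIF_SCALE = 1e5

#: default meiotic-distance cutoff for the dGIF (excludes parent-offspring,
#: sibling and grandparent-grandchild pairs)
DEFAULT_DGIF_MIN_DISTANCE = 3


class MatchingError(ValueError):
    """A case has no eligible control in its matching stratum."""


@dataclass(frozen=True)
class MatchingSpec:
    """How controls are matched to cases.

    ``match_on`` may contain ``sex``, ``birth_year`` (within
    ``birth_year_window`` years), ``birth_place`` (binarized to
    in-state/out-of-state via ``in_state_values``) and ``informativeness``
    (control must have at least ``min_generations`` of genealogy, counting
    its own generation — the same filter applied to cases).
    """

    birth_year_window: int = 5
    match_on: FrozenSet[str] = frozenset({"sex", "birth_year", "birth_place", "informativeness"})
    min_generations: int = 3
    in_state_values: FrozenSet[str] = frozenset({"in_state"})

    def __post_init__(self):
        if self.birth_year_window < 0:
            raise ValueError("birth_year_window must be >= 0")
        unknown = self.match_on - {"sex", "birth_year", "birth_place", "informativeness"}
        if unknown:
            raise ValueError(f"unknown matching attributes: {sorted(unknown)}")


@dataclass
class GIFResult:
    """Full outcome of a GIF test against matched control sets."""

    n_cases: int
    case_gif: float
    control_gifs: List[float]
    mean_control_gif: float
    p_empirical: float
    case_dgif: float
    control_dgifs: List[float]
    mean_control_dgif: float
    p_dgif: float
    #: genetic distance -> (case contribution, mean control contribution)
    distance_contributions: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    min_distance_dgif: int = DEFAULT_DGIF_MIN_DISTANCE
    n_sets: int = 0
    seed: int = 0


def _pair_stats(
    g: Genealogy, ids: Sequence[str], scale: float = GIF_SCALE
) -> Tuple[float, Dict[int, float]]:
    """(GIF, contributions-by-distance) for one id set; conserved exactly."""
    ids = sorted(set(ids))
    if len(ids) < 2:
        raise ValueError("GIF requires at least 2 individuals")
    phi = kinship_matrix(g, ids)
    n = len(ids)
    n_pairs = n * (n - 1) // 2
    rows, cols = np.triu_indices(n, k=1)
    vals = phi[rows, cols]
    gif = scale * float(vals.sum()) / n_pairs
    contrib: Dict[int, float] = defaultdict(float)
    for a, b, v in zip(rows[vals > 0], cols[vals > 0], vals[vals > 0]):
        d = genetic_distance(g, ids[a], ids[b])
        # phi > 0 implies a shared recorded ancestor, hence finite distance
        contrib[int(d)] += scale * float(v) / n_pairs
    return gif, dict(contrib)


def gif_statistic(g: Genealogy, ids: Iterable[str], scale: float = GIF_SCALE) -> float:
    """``scale`` x mean Malécot kinship over all unordered pairs in ``ids``."""
    gif, _ = _pair_stats(g, list(ids), scale)
    return gif


def distance_contributions(
    g: Genealogy, ids: Iterable[str], scale: float = GIF_SCALE
) -> Dict[int, float]:
    """Partition of the GIF sum by each contributing pair's genetic distance.

    Values sum exactly to :func:`gif_statistic`; unrelated pairs (infinite
    distance, zero kinship) contribute to no bin.
    """
    _, contrib = _pair_stats(g, list(ids), scale)
    return contrib


def dgif_statistic(
    g: Genealogy,
    ids: Iterable[str],
    min_distance: int = DEFAULT_DGIF_MIN_DISTANCE,
    scale: float = GIF_SCALE,
) -> float:
    """GIF with pairs closer than ``min_distance`` meioses zeroed out.

    The denominator keeps the full pair count so dGIF and GIF share a scale;
    ``min_distance=1`` reproduces the GIF exactly.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    gif, contrib = _pair_stats(g, list(ids), scale)
    close = sum(v for d, v in contrib.items() if d < min_distance)
    return gif - close


def _match_candidates(
    g: Genealogy, cases: Set[str], spec: MatchingSpec
) -> Dict[str, np.ndarray]:
    """Per-case arrays of eligible control ids under the matching spec."""
    pool = [ind for ind in g if ind.id not in cases]
    pool_ids = np.array([ind.id for ind in pool])
    sex = np.array([ind.sex for ind in pool])
    year = np.array([ind.birth_year for ind in pool])
    in_state = np.array([ind.birth_place in spec.in_state_values for ind in pool])
    if "informativeness" in spec.match_on:
        thr = spec.min_generations - 1
        informative = np.array([generation_depth(g, ind.id) >= thr for ind in pool])
    else:
        informative = np.ones(len(pool), dtype=bool)
    out: Dict[str, np.ndarray] = {}
    for case in sorted(cases):
        ind = g[case]
        mask = np.ones(len(pool), dtype=bool)
        if "sex" in spec.match_on:
            mask &= sex == ind.sex
        if "birth_year" in spec.match_on:
            mask &= np.abs(year - ind.birth_year) <= spec.birth_year_window
        if "birth_place" in spec.match_on:
            mask &= in_state == (ind.birth_place in spec.in_state_values)
        mask &= informative
        cands = pool_ids[mask]
        if cands.size == 0:
            stratum = (
                f"sex={ind.sex}, birth_year={ind.birth_year}±{spec.birth_year_window}, "
                f"birth_place={'in' if ind.birth_place in spec.in_state_values else 'out'}_state"
            )
            raise MatchingError(f"case {case!r} has no eligible control in stratum ({stratum})")
        out[case] = cands
    return out


def sample_matched_controls(
    g: Genealogy,
    cases: Iterable[str],
    spec: MatchingSpec = MatchingSpec(),
    n_sets: int = 1000,
    seed: int = 0,
) -> List[List[str]]:
    """Draw ``n_sets`` control sets, one matched control per case.

    Controls are sampled uniformly from each case's matching stratum,
    without replacement within a set (with replacement across sets); cases
    are never eligible.  Deterministic given ``seed``: each set consumes its
    own derived random stream, so results do not depend on evaluation order.
    """
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    case_set = set(cases)
    if not case_set:
        raise ValueError("need at least one case")
    candidates = _match_candidates(g, case_set, spec)
    case_order = sorted(case_set)
    streams = np.random.SeedSequence(seed).spawn(n_sets)
    sets: List[List[str]] = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        used: Set[str] = set()
        chosen: List[str] = []
        for case in rng.permutation(case_order):
            cands = candidates[case]
            pick = cands[rng.integers(cands.size)]
            if pick in used:  # collision: scan a fresh permutation
                pick = None
                for alt in cands[rng.permutation(cands.size)]:
                    if alt not in used:
                        pick = alt
                        break
                if pick is None:
                    raise MatchingError(
                        f"case {case!r}: all {cands.size} eligible controls already "
                        "used in this set"
                    )
            used.add(pick)
            chosen.append(str(pick))
        sets.append(sorted(chosen))
    return sets


def _mean_contributions(maps: List[Dict[int, float]]) -> Dict[int, float]:
    total: Dict[int, float] = defaultdict(float)
    for m in maps:
        for d, v in m.items():
            total[d] += v
    return {d: v / len(maps) for d, v in total.items()}


def _empirical_p(case_stat: float, control_stats: Sequence[float]) -> float:
    """One-sided add-one empirical p: (1 + #{controls >= case}) / (1 + n)."""
    exceed = sum(1 for c in control_stats if c >= case_stat)
    return (1 + exceed) / (1 + len(control_stats))


def gif_test(
    g: Genealogy,
    cases: Iterable[str],
    spec: MatchingSpec = MatchingSpec(),
    n_sets: int = 1000,
    min_distance_dgif: int = DEFAULT_DGIF_MIN_DISTANCE,
    seed: int = 0,
    scale: float = GIF_SCALE,
) -> GIFResult:
    """Run the full GIF/dGIF excess-relatedness test against matched controls."""
    case_ids = sorted(set(cases))
    if len(case_ids) < 2:
        raise ValueError("GIF test requires at least 2 cases")
    case_gif, case_contrib = _pair_stats(g, case_ids, scale)
    case_close = sum(v for d, v in case_contrib.items() if d < min_distance_dgif)
    case_dgif = case_gif - case_close

    control_sets = sample_matched_controls(g, case_ids, spec, n_sets, seed)
    control_gifs: List[float] = []
    control_dgifs: List[float] = []
    control_maps: List[Dict[int, float]] = []
    for cset in control_sets:
        gif, contrib = _pair_stats(g, cset, scale)
        close = sum(v for d, v in contrib.items() if d < min_distance_dgif)
        control_gifs.append(gif)
        control_dgifs.append(gif - close)
        control_maps.append(contrib)

    mean_control = _mean_contributions(control_maps)
    distances = sorted(set(case_contrib) | set(mean_control))
    return GIFResult(
        n_cases=len(case_ids),
        case_gif=case_gif,
        control_gifs=control_gifs,
        mean_control_gif=float(np.mean(control_gifs)),
        p_empirical=_empirical_p(case_gif, control_gifs),
        case_dgif=case_dgif,
        control_dgifs=control_dgifs,
        mean_control_dgif=float(np.mean(control_dgifs)),
        p_dgif=_empirical_p(case_dgif, control_dgifs),
        distance_contributions={
            d: (case_contrib.get(d, 0.0), mean_control.get(d, 0.0)) for d in distances
        },
        min_distance_dgif=min_distance_dgif,
        n_sets=n_sets,
        seed=seed,
    )
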