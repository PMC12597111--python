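"""Shared fixtures: hand-built pedigrees exercising every relationship class,
and the expensive null-calibration rate reused by two acceptance checks."""

import pytest

from famclust import Genealogy, Individual


def build_genealogy(rows, validate=True):
    """rows: (id, father, mother, sex, birth_year[, affected]) tuples."""
    individuals = []
    for row in rows:
        ind_id, father, mother, sex, year = row[:5]
        affected = bool(row[5]) if len(row) > 5 else False
        individuals.append(
            Individual(
                id=ind_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                birth_year=year,
                birth_place="in_state" if father else "out_of_state",
                affected=affected,
            )
        )
    return Genealogy(individuals, validate=validate)


@pytest.fixture
def trio():
    """Founder couple and one child."""
    return build_genealogy(
        [
            ("dad", None, None, "M", 1900),
            ("mom", None, None, "F", 1902),
            ("kid", "dad", "mom", "M", 1930),
        ]
    )


EXTENDED_ROWS = [
    # founders
    ("gpa", None, None, "M", 1870),
    ("gma", None, None, "F", 1872),
    # their children: two full siblings
    ("dad", "gpa", "gma", "M", 1900),
    ("uncle", "gpa", "gma", "M", 1903),
    # spouses (married in)
    ("mom", None, None, "F", 1902),
    ("aunt", None, None, "F", 1905),
    # grandchildren: sibs kid1/kid2; first cousin cousin1
    ("kid1", "dad", "mom", "M", 1930),
    ("kid2", "dad", "mom", "F", 1932),
    ("cousin1", "uncle", "aunt", "F", 1934),
    # next generation: children of kid1 and cousin1 are second cousins
    ("wife1", None, None, "F", 1931),
    ("husb1", None, None, "M", 1933),
    ("gkid1", "kid1", "wife1", "M", 1960),
    ("gkid2", "husb1", "cousin1", "F", 1962),
    # half-siblings: dad has a child with a second partner
    ("mom2", None, None, "F", 1904),
    ("halfsib", "dad", "mom2", "M", 1935),
]


@pytest.fixture
def extended_family():
    """Four generations covering sibs, half-sibs, avuncular, first and second
    cousins, grandparents and great-grandparents."""
    return build_genealogy(EXTENDED_ROWS)


@pytest.fixture
def inbred_pedigree():
    """Full-sibling mating: the child's self-kinship is 0.625."""
    return build_genealogy(
        [
            ("f", None, None, "M", 1880),
            ("m", None, None, "F", 1882),
            ("s1", "f", "m", "M", 1910),
            ("s2", "f", "m", "F", 1912),
            ("loop_child", "s1", "s2", "M", 1940),
        ]
    )


def five_generation_line(n_gen=5, affected_gens=()):
    """Complete ancestry: generation k (1-based) has 2**(n_gen-k) members and
    every member of generation k has depth k-1.  One line of descent."""
    rows = []
    prev = []
    for gen in range(1, n_gen + 1):
        width = 2 ** (n_gen - gen)
        cur = []
        for j in range(width):
            ind_id = f"g{gen}n{j}"
            sex = "M" if j % 2 == 0 else "F"
            if gen == 1:
                rows.append((ind_id, None, None, sex, 1800, gen in affected_gens))
            else:
                rows.append(
                    (ind_id, prev[2 * j], prev[2 * j + 1], sex, 1800 + 25 * (gen - 1),
                     gen in affected_gens)
                )
            cur.append(ind_id)
        prev = cur
    return build_genealogy(rows)


@pytest.fixture(scope="session")
def null_gif_rejection_rate():
    """Empirical type-I error of the GIF test at alpha = 0.05, measured over
    200 null replicates (~2,000-person genealogies, 0.8% phenotype rate,
    200 matched control sets each).  Session-scoped: reused by the
    calibration check and as the reference rate for the power check."""
    import famclust as fc
    from famclust import MatchingError
    from famclust.simulate import SimParams

    rejections = 0
    used = 0
    rep = 0
    while used < 200 and rep < 240:
        g = fc.simulate_genealogy(SimParams(seed=10_000 + rep))
        fc.assign_phenotypes_null(g, 0.008, seed=20_000 + rep)
        cases = fc.informative_cases(g, 3)
        rep += 1
        if len(cases) < 2:
            continue
        try:
            res = fc.gif_test(g, cases, n_sets=200, seed=30_000 + rep)
        except MatchingError:
            # a case at the extreme tail of the birth-year distribution can
            # have an empty matching stratum at this population size; such
            # replicates carry no information about relatedness and are skipped
            continue
        used += 1
        if res.p_empirical <= 0.05:
            rejections += 1
    assert used == 200, "could not assemble 200 valid null replicates"
    return rejections / used
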