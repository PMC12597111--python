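"""Pedigree data model, PED-like I/O, validation, and the informativeness filter.

A :class:`Genealogy` is a directed acyclic graph of parent links over
:class:`Individual` records.  Individuals carry the attributes used for
control matching and cohort construction (sex, birth year, birth place) plus
an affection flag.  Files are tab- or whitespace-delimited with columns

    id  father_id  mother_id  sex(M/F)  birth_year  birth_place  affected(0/1)

where ``0`` (or empty/NA) denotes a missing parent.  A header line is
optional and detected by a non-numeric ``birth_year`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx

__all__ = [
    "Individual",
    "Genealogy",
    "ValidationReport",
    "PedigreeError",
    "ParseError",
    "ValidationError",
    "read_pedigree",
    "write_pedigree",
    "generation_depth",
    "informative_cases",
]

#: tokens accepted as "no recorded parent"
MISSING_PARENT = {"", "0", ".", "NA", "na", "None"}

_SEX_ALIASES = {
    "m": "M",
    "male": "M",
    "1": "M",
    "f": "F",
    "female": "F",
    "2": "F",
}

COLUMNS = ("id", "father_id", "mother_id", "sex", "birth_year", "birth_place", "affected")


class PedigreeError(ValueError):
    """Base class for pedigree file and structure errors."""


class ParseError(PedigreeError):
    """A malformed row in a pedigree file; names the offending line."""


class ValidationError(PedigreeError):
    """Structural validation failed; carries the full report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(f"[{r}] {i}: {m}" for r, i, m in report.errors[:10])
        more = "" if len(report.errors) <= 10 else f" (+{len(report.errors) - 10} more)"
        super().__init__(f"pedigree validation failed: {lines}{more}")


@dataclass
class Individual:
    """One genealogy member.

    ``father_id``/``mother_id`` are ``None`` when unrecorded.  ``sex`` is
    ``"M"`` or ``"F"`` (required: matching and parent-sex checks need it).
    ``birth_place`` is a free categorical; it is binarized to in-state /
    out-of-state only where cohorts are built.
    """

    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    birth_year: int
    birth_place: str
    affected: bool = False

    def parent_ids(self) -> Tuple[str, ...]:
        """Recorded parent ids (0, 1 or 2 of them)."""
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)


@dataclass
class ValidationReport:
    """Outcome of structural validation: a list of (rule, individual id, message)."""

    errors: List[Tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        if self.ok:
            return "OK: pedigree is valid"
        out = [f"{len(self.errors)} validation error(s):"]
        out += [f"  [{rule}] {ind}: {msg}" for rule, ind, msg in self.errors]
        return "\n".join(out)


class Genealogy:
    """A validated collection of individuals with parent links.

    Construction validates by default (referential integrity, parent sexes,
    acyclicity, birth-year ordering) and raises :class:`ValidationError` on
    failure.  Pass ``validate=False`` to build an unvalidated instance and
    call :meth:`validate` to obtain the report instead.

    Derived structure (children map, topological order, kinship caches) is
    computed lazily and cached; the ``affected`` flags may be rewritten via
    :meth:`set_affected` without invalidating structural caches.
    """

    def __init__(self, individuals: Iterable[Individual], validate: bool = True):
        self._ind: Dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._ind:
                raise ValidationError(
                    ValidationReport([("unique-id", ind.id, "duplicate individual id")])
                )
            self._ind[ind.id] = ind
        # lazy caches (structure only; never touched by affected-flag changes)
        self._children: Optional[Dict[str, List[str]]] = None
        self._topo: Optional[List[str]] = None
        self._gen_index: Optional[Dict[str, int]] = None
        self._depth: Dict[str, int] = {}
        self._phi_cache: Dict[Tuple[str, str], float] = {}
        self._anc_depths: Dict[str, Dict[str, int]] = {}
        self._additive = None  # (index map, matrix) from kinship module
        if validate:
            report = self.validate()
            if not report.ok:
                raise ValidationError(report)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._ind)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._ind.values())

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._ind

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self._ind[ind_id]
        except KeyError:
            raise KeyError(f"unknown individual id: {ind_id!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Genealogy) and self._ind == other._ind

    @property
    def ids(self) -> List[str]:
        return list(self._ind)

    # -- validation ---------------------------------------------------------

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        for ind in self:
            if ind.sex not in ("M", "F"):
                report.errors.append(("sex", ind.id, f"sex must be M or F, got {ind.sex!r}"))
            for role, pid, want in (("father", ind.father_id, "M"), ("mother", ind.mother_id, "F")):
                if pid is None:
                    continue
                parent = self._ind.get(pid)
                if parent is None:
                    report.errors.append(
                        ("dangling-parent", ind.id, f"{role}_id {pid!r} not in genealogy")
                    )
                elif parent.sex != want:
                    report.errors.append(
                        ("parent-sex", ind.id, f"{role} {pid!r} is not {want}")
                    )
                elif parent.birth_year >= ind.birth_year:
                    report.errors.append(
                        (
                            "birth-order",
                            ind.id,
                            f"born {ind.birth_year}, not after {role} {pid!r} "
                            f"({parent.birth_year})",
                        )
                    )
        graph = nx.DiGraph()
        graph.add_nodes_from(self._ind)
        for ind in self:
            for pid in ind.parent_ids():
                if pid in self._ind:
                    graph.add_edge(pid, ind.id)
        if not nx.is_directed_acyclic_graph(graph):
            for cyc in nx.simple_cycles(graph):
                report.errors.append(
                    ("cycle", cyc[0], "individual is its own ancestor: " + " -> ".join(cyc))
                )
        return report

    # -- derived structure --------------------------------------------------

    def children_map(self) -> Dict[str, List[str]]:
        """id -> list of children ids (both-parent links collapse to one entry)."""
        if self._children is None:
            cm: Dict[str, List[str]] = {i: [] for i in self._ind}
            for ind in self:
                for pid in ind.parent_ids():
                    cm[pid].append(ind.id)
            self._children = cm
        return self._children

    def founders(self) -> List[str]:
        """Individuals with no recorded parents."""
        return [i.id for i in self if not i.parent_ids()]

    def topological_order(self) -> List[str]:
        """Ids ordered so every parent precedes its children."""
        if self._topo is None:
            graph = nx.DiGraph()
            graph.add_nodes_from(self._ind)
            for ind in self:
                for pid in ind.parent_ids():
                    graph.add_edge(pid, ind.id)
            self._topo = list(nx.topological_sort(graph))
        return self._topo

    def generation_index(self) -> Dict[str, int]:
        """id -> longest ancestral chain length (founders 0)."""
        if self._gen_index is None:
            gi: Dict[str, int] = {}
            for i in self.topological_order():
                parents = self._ind[i].parent_ids()
                gi[i] = 1 + max(gi[p] for p in parents) if parents else 0
            self._gen_index = gi
        return self._gen_index

    # -- phenotype ----------------------------------------------------------

    def set_affected(self, case_ids: Iterable[str]) -> None:
        """Rewrite affection status: exactly ``case_ids`` become affected."""
        cases = set(case_ids)
        unknown = cases - set(self._ind)
        if unknown:
            raise KeyError(f"unknown individual id(s): {sorted(unknown)[:5]}")
        for ind in self:
            ind.affected = ind.id in cases

    def affected_ids(self) -> Set[str]:
        return {ind.id for ind in self if ind.affected}


# -- generation depth and informativeness -----------------------------------


def generation_depth(g: Genealogy, ind_id: str) -> int:
    """Number of complete ancestral generations recorded above ``ind_id``.

    0 when any parent is unrecorded; otherwise ``1 + min(depth(father),
    depth(mother))`` — both lineages must be present for a generation to
    count as complete.
    """
    if ind_id not in g:
        raise KeyError(f"unknown individual id: {ind_id!r}")
    memo = g._depth
    stack = [ind_id]
    while stack:
        i = stack[-1]
        if i in memo:
            stack.pop()
            continue
        ind = g[i]
        if ind.father_id is None or ind.mother_id is None:
            memo[i] = 0
            stack.pop()
            continue
        pending = [p for p in (ind.father_id, ind.mother_id) if p not in memo]
        if pending:
            stack.extend(pending)
        else:
            memo[i] = 1 + min(memo[ind.father_id], memo[ind.mother_id])
            stack.pop()
    return memo[ind_id]


def informative_cases(g: Genealogy, min_generations: int = 3, count_self: bool = True) -> Set[str]:
    """Affected individuals with at least ``min_generations`` of genealogy.

    By default the individual's own generation counts as one of the
    ``min_generations`` (UPDB-style usage: "3 generations" = self + parents +
    grandparents, i.e. depth >= 2).  With ``count_self=False`` the threshold
    is read as ancestral generations only (depth >= min_generations).
    """
    if min_generations < 0:
        raise ValueError("min_generations must be >= 0")
    threshold = min_generations - 1 if count_self else min_generations
    return {
        ind.id
        for ind in g
        if ind.affected and generation_depth(g, ind.id) >= threshold
    }


# -- file I/O ----------------------------------------------------------------


def _parse_row(fields: List[str], lineno: int) -> Individual:
    if len(fields) != len(COLUMNS):
        raise ParseError(
            f"line {lineno}: expected {len(COLUMNS)} columns {COLUMNS}, got {len(fields)}"
        )
    ind_id, fid, mid, sex_raw, year_raw, place, aff_raw = fields
    sex = _SEX_ALIASES.get(sex_raw.strip().lower())
    if sex is None:
        raise ParseError(f"line {lineno}: unknown sex {sex_raw!r} (use M/F); sex is required")
    try:
        year = int(year_raw)
    except ValueError:
        raise ParseError(f"line {lineno}: birth_year {year_raw!r} is not an integer") from None
    aff = aff_raw.strip().lower()
    if aff in ("1", "true", "yes"):
        affected = True
    elif aff in ("0", "false", "no", ""):
        affected = False
    else:
        raise ParseError(f"line {lineno}: affected flag {aff_raw!r} must be 0/1")
    return Individual(
        id=ind_id,
        father_id=None if fid.strip() in MISSING_PARENT else fid.strip(),
        mother_id=None if mid.strip() in MISSING_PARENT else mid.strip(),
        sex=sex,
        birth_year=year,
        birth_place=place.strip(),
        affected=affected,
    )


def read_pedigree(path) -> Genealogy:
    """Read and validate a PED-like tab/whitespace-delimited pedigree file.

    Raises :class:`ParseError` for malformed rows (naming the line) and
    :class:`ValidationError` for structural problems (dangling parents,
    cycles, parent-sex or birth-order violations).  Row order is irrelevant.
    """
    rows: List[Individual] = []
    first_data_line = True
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if first_data_line:
                first_data_line = False
                # header detection: non-numeric birth_year field
                if len(fields) == len(COLUMNS):
                    try:
                        int(fields[4])
                    except ValueError:
                        continue
            rows.append(_parse_row(fields, lineno))
    return Genealogy(rows)


def write_pedigree(g: Genealogy, path) -> None:
    """Write the canonical form: header, rows sorted by id, tab-delimited."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for ind_id in sorted(g.ids):
            ind = g[ind_id]
            fh.write(
                "\t".join(
                    [
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        ind.sex,
                        str(ind.birth_year),
                        ind.birth_place,
                        "1" if ind.affected else "0",
                    ]
                )
                + "\n"
            )
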