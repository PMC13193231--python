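"""Pedigree data model, validation, family restructuring, and lineage extraction.

The central container is :class:`PedigreeTable`, an ordered roster of
:class:`Individual` records with an id index.  A pedigree is a directed acyclic
structure: founders (both parents missing) sit at the top and every other
individual points at a mother and/or father inside the table.

All structural problems (self-parenting, sex-inconsistent parents, dangling
parent ids, cycles, inconsistent twin groups) are *reported* by
:func:`validate` rather than raised, so that callers can decide how strict to
be; downstream stages (layout, relatedness) require a clean report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx
import pandas as pd

#: Codes normalised to a missing parent on ingestion.
MISSING_CODES = {"", "0", "NA", "na", "N/A", None}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Zygosity(str, Enum):
    MZ = "MZ"
    DZ = "DZ"


def parse_sex(value: object) -> Sex:
    """Normalise the common sex encodings: {1, M, male} / {2, F, female}."""
    s = str(value).strip().lower()
    if s in {"1", "m", "male"}:
        return Sex.MALE
    if s in {"2", "f", "female"}:
        return Sex.FEMALE
    return Sex.UNKNOWN


def parse_affected(value: object) -> Optional[bool]:
    s = str(value).strip().lower()
    if s in {"1", "yes", "true", "affected", "2"}:
        # PLINK case/control codes 2=case under the 1/2 convention are not
        # auto-detected; plain CSV uses 1/yes/true.
        return True
    if s in {"0", "no", "false", "unaffected"}:
        return False
    return None


@dataclass
class Individual:
    """One pedigree member.

    ``momID``/``dadID`` are ``None`` when the parent is unrecorded.  ``famID``
    is ``None`` until :func:`assign_families` labels connected components.
    ``affected`` is a tristate: ``True``/``False``/``None`` (unknown).
    ``placeholder`` marks synthetic parents inserted by :func:`pad_founders`
    so renderers can style them distinctly.
    """

    personID: str
    momID: Optional[str] = None
    dadID: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    famID: Optional[str] = None
    affected: Optional[bool] = None
    twinID: Optional[str] = None
    zygosity: Optional[Zygosity] = None
    phenotypes: Dict[str, float] = field(default_factory=dict)
    placeholder: bool = False

    @property
    def is_founder(self) -> bool:
        return self.momID is None and self.dadID is None


class PedigreeTable:
    """Ordered collection of individuals with unique ids.

    Raises ``ValueError`` on duplicate personIDs at construction; every other
    structural issue is left to :func:`validate`.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: List[Individual] = list(individuals)
        self.idIndex: Dict[str, int] = {}
        dups = []
        for i, ind in enumerate(self.individuals):
            if ind.personID in self.idIndex:
                dups.append(ind.personID)
            self.idIndex[ind.personID] = i
        if dups:
            raise ValueError(f"duplicate personID values: {sorted(set(dups))}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __contains__(self, personID: str) -> bool:
        return personID in self.idIndex

    def get(self, personID: str) -> Individual:
        try:
            return self.individuals[self.idIndex[personID]]
        except KeyError:
            raise KeyError(f"unknown personID: {personID!r}") from None

    @property
    def ids(self) -> List[str]:
        return [ind.personID for ind in self.individuals]

    def copy(self) -> "PedigreeTable":
        return PedigreeTable(
            replace(ind, phenotypes=dict(ind.phenotypes)) for ind in self.individuals
        )

    # -- derived structure ---------------------------------------------------
    def children_of(self, personID: str) -> List[Individual]:
        return [
            ind
            for ind in self.individuals
            if personID in (ind.momID, ind.dadID)
        ]

    def matings(self) -> Dict[Tuple[Optional[str], Optional[str]], List[str]]:
        """Map (momID, dadID) -> child ids, for individuals with any parent."""
        out: Dict[Tuple[Optional[str], Optional[str]], List[str]] = {}
        for ind in self.individuals:
            if ind.momID is None and ind.dadID is None:
                continue
            out.setdefault((ind.momID, ind.dadID), []).append(ind.personID)
        return out

    def phenotype_names(self) -> List[str]:
        names: List[str] = []
        for ind in self.individuals:
            for k in ind.phenotypes:
                if k not in names:
                    names.append(k)
        return names

    # -- frames --------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        pheno_names = self.phenotype_names()
        for ind in self.individuals:
            row = {
                "personID": ind.personID,
                "momID": ind.momID if ind.momID is not None else "",
                "dadID": ind.dadID if ind.dadID is not None else "",
                "sex": ind.sex.value,
                "famID": ind.famID if ind.famID is not None else "",
                "affected": {True: "yes", False: "no", None: ""}[ind.affected],
                "twinID": ind.twinID if ind.twinID is not None else "",
                "zygosity": ind.zygosity.value if ind.zygosity else "",
                "placeholder": "1" if ind.placeholder else "",
            }
            for name in pheno_names:
                v = ind.phenotypes.get(name)
                row[name] = "" if v is None else repr(float(v))
            rows.append(row)
        cols = [
            "personID", "momID", "dadID", "sex", "famID",
            "affected", "twinID", "zygosity", "placeholder",
        ] + pheno_names
        return pd.DataFrame(rows, columns=cols)


@dataclass
class ValidationReport:
    errors: List[Tuple[str, str, str]] = field(default_factory=list)
    warnings: List[Tuple[str, str, str]] = field(default_factory=list)

    @property
    def isValid(self) -> bool:
        return not self.errors

    def error_codes(self) -> Set[str]:
        return {code for code, _, _ in self.errors}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{len(self.errors)} errors, {len(self.warnings)} warnings"]
        for code, pid, msg in self.errors:
            lines.append(f"  ERROR {code} [{pid}]: {msg}")
        for code, pid, msg in self.warnings:
            lines.append(f"  WARN  {code} [{pid}]: {msg}")
        return "\n".join(lines)


def parent_graph(ped: PedigreeTable) -> nx.DiGraph:
    """Directed graph with parent -> child edges (only in-table parents)."""
    g = nx.DiGraph()
    g.add_nodes_from(ped.ids)
    for ind in ped:
        for pid in (ind.momID, ind.dadID):
            if pid is not None and pid in ped:
                g.add_edge(pid, ind.personID)
    return g


def validate(ped: PedigreeTable) -> ValidationReport:
    """Report every structural violation; never mutates the input.

    Error codes: ``SELF_PARENT``, ``PARENT_SEX_MISMATCH``, ``DANGLING_PARENT``,
    ``PARENT_CYCLE``, ``TWIN_GROUP_SIZE``, ``TWIN_PARENT_MISMATCH``,
    ``TWIN_ZYGOSITY_CONFLICT``.  Warning codes: ``PARENT_SEX_UNKNOWN``.
    """
    rep = ValidationReport()
    for ind in ped:
        if ind.personID == ind.momID or ind.personID == ind.dadID:
            rep.errors.append(
                ("SELF_PARENT", ind.personID, "individual listed as own parent")
            )
        for pid, want, slot in ((ind.momID, Sex.FEMALE, "mother"),
                                (ind.dadID, Sex.MALE, "father")):
            if pid is None or pid == ind.personID:
                continue
            if pid not in ped:
                rep.errors.append(
                    ("DANGLING_PARENT", ind.personID,
                     f"{slot} id {pid!r} not in table")
                )
                continue
            psex = ped.get(pid).sex
            if psex is Sex.UNKNOWN:
                rep.warnings.append(
                    ("PARENT_SEX_UNKNOWN", ind.personID,
                     f"{slot} {pid!r} has unknown sex")
                )
            elif psex is not want:
                rep.errors.append(
                    ("PARENT_SEX_MISMATCH", ind.personID,
                     f"{slot} {pid!r} recorded as {psex.value}")
                )

    g = parent_graph(ped)
    try:
        cycles = list(nx.simple_cycles(g))
    except nx.NetworkXError:  # pragma: no cover
        cycles = []
    for cyc in cycles:
        rep.errors.append(
            ("PARENT_CYCLE", cyc[0], "ancestry cycle: " + " -> ".join(cyc))
        )

    groups: Dict[str, List[Individual]] = {}
    for ind in ped:
        if ind.twinID is not None:
            groups.setdefault(ind.twinID, []).append(ind)
    for tid, members in groups.items():
        if len(members) < 2:
            rep.errors.append(
                ("TWIN_GROUP_SIZE", members[0].personID,
                 f"twinID {tid!r} has a single member")
            )
        parents = {(m.momID, m.dadID) for m in members}
        if len(parents) > 1:
            rep.errors.append(
                ("TWIN_PARENT_MISMATCH", members[0].personID,
                 f"twinID {tid!r} members have different parents")
            )
        zygs = {m.zygosity for m in members if m.zygosity is not None}
        if len(zygs) > 1:
            rep.errors.append(
                ("TWIN_ZYGOSITY_CONFLICT", members[0].personID,
                 f"twinID {tid!r} mixes zygosity codes")
            )
    return rep


def pad_founders(ped: PedigreeTable, mode: str = "both_or_none") -> PedigreeTable:
    """Give single-parent individuals a synthetic opposite-sex co-parent.

    The connection geometry assumes two-parent matings; under
    ``both_or_none`` every individual ends up with either zero or two known
    parents.  Placeholders share the known parent's other children (one
    placeholder per half-sibship) and are flagged via ``placeholder=True``.
    """
    if mode == "none":
        return ped
    if mode != "both_or_none":
        raise ValueError(f"unknown pad mode: {mode!r}")

    out = ped.copy()
    counter = itertools.count(1)
    # one placeholder per (known parent, missing slot) mating
    created: Dict[Tuple[str, str], str] = {}
    new_inds: List[Individual] = []
    for ind in out:
        has_mom, has_dad = ind.momID is not None, ind.dadID is not None
        if has_mom == has_dad:
            continue
        if has_mom:
            key = (ind.momID, "dad")
            if key not in created:
                pid = _fresh_id(out, "ph_dad", counter)
                created[key] = pid
                new_inds.append(Individual(pid, sex=Sex.MALE, famID=ind.famID,
                                           placeholder=True))
            ind.dadID = created[key]
        else:
            key = (ind.dadID, "mom")
            if key not in created:
                pid = _fresh_id(out, "ph_mom", counter)
                created[key] = pid
                new_inds.append(Individual(pid, sex=Sex.FEMALE, famID=ind.famID,
                                           placeholder=True))
            ind.momID = created[key]
    if not new_inds:
        return out
    return PedigreeTable(list(out) + new_inds)


def _fresh_id(ped: PedigreeTable, stem: str, counter: itertools.count) -> str:
    while True:
        pid = f"{stem}{next(counter)}"
        if pid not in ped:
            return pid


def family_graph(ped: PedigreeTable) -> nx.Graph:
    """Undirected graph whose edges are parent-child and co-parent links."""
    g = nx.Graph()
    g.add_nodes_from(ped.ids)
    for ind in ped:
        present = [p for p in (ind.momID, ind.dadID) if p is not None and p in ped]
        for p in present:
            g.add_edge(p, ind.personID)
        if len(present) == 2:
            g.add_edge(present[0], present[1])
    return g


def assign_families(ped: PedigreeTable) -> PedigreeTable:
    """Label connected components with deterministic famIDs.

    The component containing the smallest personID (string sort order) gets
    label "1", the next smallest unlabelled component "2", and so on —
    reapplication and row permutation both leave the labelling unchanged.
    """
    g = family_graph(ped)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    out = ped.copy()
    for label, comp in enumerate(comps, start=1):
        for pid in comp:
            out.get(pid).famID = str(label)
    return out


def extract_lineage(ped: PedigreeTable, person: str, line: str = "maternal") -> Set[str]:
    """Matriline (or patriline) through ``person``.

    The closure of {person} under mother links upward and mother-child links
    downward — i.e. everyone sharing the person's matrilineal founder.
    ``line='paternal'`` is symmetric via father links.
    """
    if person not in ped:
        raise KeyError(f"unknown personID: {person!r}")
    if line not in ("maternal", "paternal"):
        raise ValueError(f"line must be 'maternal' or 'paternal', got {line!r}")

    def parent_of(ind: Individual) -> Optional[str]:
        return ind.momID if line == "maternal" else ind.dadID

    # climb to the lineage founder
    root = person
    seen = {root}
    while True:
        p = parent_of(ped.get(root))
        if p is None or p not in ped or p in seen:
            break
        root = p
        seen.add(root)

    # flood matrilineal/patrilineal descent from the founder
    out: Set[str] = set()
    frontier = [root]
    while frontier:
        cur = frontier.pop()
        if cur in out:
            continue
        out.add(cur)
        for child in ped.children_of(cur):
            if parent_of(child) == cur:
                frontier.append(child.personID)
    return out
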