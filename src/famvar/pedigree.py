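"""Pedigree ingestion, validation, and kinship computation.

A pedigree is a set of individuals with optional father/mother links and a
recorded sex. Individuals are partitioned into *blocks*: connected components
of the graph whose edges join parents to children and co-members of the same
family (household). Blocks are the unit over which the variance-components
likelihood factorises, so both the additive relationship matrix ``2*Phi`` and
the household-sharing matrix are block-diagonal by construction.

Kinship coefficients are computed by the recursive tabular method with
founders assumed non-inbred and mutually unrelated. ``phi[i, i]`` equals
``0.5 * (1 + f_i)`` where ``f_i`` is the kinship of the parents, and for
``j`` processed before ``i`` (ancestors first)::

    phi[i, j] = 0.5 * (phi[father_i, j] + phi[mother_i, j])

with an unknown parent contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "DuplicateIdError",
    "ParentSexError",
    "MissingParentError",
    "PedigreeCycleError",
    "read_pedigree",
    "family_blocks",
    "kinship_matrix",
]


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeError):
    """The same individual id appears more than once."""


class ParentSexError(PedigreeError):
    """A father is not male, or a mother is not female."""


class MissingParentError(PedigreeError):
    """A parent id is referenced but no such individual exists."""


class PedigreeCycleError(PedigreeError):
    """An individual is its own ancestor (includes self-parenting)."""


_MISSING_PARENT = {None, "", "0", 0, "na", "nan", "none"}

_SEX_CODES = {
    "1": "male",
    "2": "female",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
}


def _norm_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if isinstance(value, float) and value == int(value):
        s = str(int(value))
    return None if s.lower() in _MISSING_PARENT else s


def _norm_sex(value) -> str:
    s = str(value).strip().lower()
    if isinstance(value, float) and not np.isnan(value) and value == int(value):
        s = str(int(value))
    try:
        return _SEX_CODES[s]
    except KeyError:
        raise PedigreeError(f"unrecognised sex code: {value!r}") from None


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are ``None`` when unknown."""

    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"


class Pedigree:
    """Validated collection of individuals with block structure.

    Parameters
    ----------
    individuals
        Members in input row order. Parents referenced must be present;
        an individual with only one recorded parent keeps the other as
        unknown (implicitly a unique, unrelated founder).
    """

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals = list(individuals)
        self._index = {}
        for pos, ind in enumerate(self.individuals):
            if ind.id in self._index:
                raise DuplicateIdError(f"duplicate individual id: {ind.id!r}")
            self._index[ind.id] = pos
        self._validate_parents()
        self._check_acyclic()
        self.blocks = self._connected_components()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        cols = list(df.columns[:5])
        inds = [
            Individual(
                id=str(row[cols[1]]).strip(),
                family_id=str(row[cols[0]]).strip(),
                father_id=_norm_parent(row[cols[2]]),
                mother_id=_norm_parent(row[cols[3]]),
                sex=_norm_sex(row[cols[4]]),
            )
            for row in df.to_dict("records")
        ]
        return cls(inds)

    # -- validation --------------------------------------------------------

    def _validate_parents(self) -> None:
        for ind in self.individuals:
            for pid, role, want in (
                (ind.father_id, "father", "male"),
                (ind.mother_id, "mother", "female"),
            ):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise MissingParentError(
                        f"{role} {pid!r} of {ind.id!r} is not in the pedigree"
                    )
                parent = self.individuals[self._index[pid]]
                if parent.sex != want:
                    raise ParentSexError(
                        f"{role} {pid!r} of {ind.id!r} has sex {parent.sex}"
                    )

    def _check_acyclic(self) -> None:
        # iterative DFS over child -> parent edges; colour 1 = on stack
        colour = {}
        for start in self._index:
            if colour.get(start):
                continue
            stack = [(start, iter(self._parent_ids(start)))]
            colour[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    c = colour.get(nxt, 0)
                    if c == 1:
                        raise PedigreeCycleError(
                            f"individual {nxt!r} is its own ancestor"
                        )
                    if c == 0:
                        colour[nxt] = 1
                        stack.append((nxt, iter(self._parent_ids(nxt))))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = 2
                    stack.pop()

    def _parent_ids(self, iid: str) -> list[str]:
        ind = self.individuals[self._index[iid]]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    # -- structure ---------------------------------------------------------

    def _connected_components(self) -> list[np.ndarray]:
        """Components of the union of parent-child and same-family edges."""
        n = len(self.individuals)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        fam_first: dict[str, int] = {}
        for pos, ind in enumerate(self.individuals):
            for pid in self._parent_ids(ind.id):
                union(pos, self._index[pid])
            if ind.family_id in fam_first:
                union(pos, fam_first[ind.family_id])
            else:
                fam_first[ind.family_id] = pos
        groups: dict[int, list[int]] = {}
        for pos in range(n):
            groups.setdefault(find(pos), []).append(pos)
        # keep blocks ordered by first appearance, rows in input order
        return [
            np.array(sorted(members), dtype=np.intp)
            for _, members in sorted(groups.items(), key=lambda kv: min(kv[1]))
        ]

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def sexes(self) -> np.ndarray:
        """1 for male, 0 for female, aligned to input order."""
        return np.array(
            [1 if ind.sex == "male" else 0 for ind in self.individuals],
            dtype=np.int8,
        )

    def position(self, iid: str) -> int:
        return self._index[iid]

    # -- kinship -----------------------------------------------------------

    def kinship(self, members: Iterable[int] | None = None) -> np.ndarray:
        """Kinship matrix ``phi`` for ``members`` (positions; default all).

        Entries are re-indexed to the order given in ``members``. Ancestors
        outside ``members`` still contribute through the recursion, so the
        result is independent of which subset is requested.
        """
        members = (
            np.arange(len(self.individuals), dtype=np.intp)
            if members is None
            else np.asarray(list(members), dtype=np.intp)
        )
        # restrict the recursion to the ancestral closure of the request
        needed: set[int] = set()
        stack = list(members)
        while stack:
            pos = stack.pop()
            if pos in needed:
                continue
            needed.add(pos)
            for pid in self._parent_ids(self.individuals[pos].id):
                stack.append(self._index[pid])
        order = self._topological(sorted(needed))
        rank = {pos: k for k, pos in enumerate(order)}
        m = len(order)
        phi = np.zeros((m, m))
        for i_rank, pos in enumerate(order):
            ind = self.individuals[pos]
            fp = rank.get(self._index.get(ind.father_id, -1), None) if ind.father_id else None
            mp = rank.get(self._index.get(ind.mother_id, -1), None) if ind.mother_id else None
            self_kin = 0.5
            if fp is not None and mp is not None:
                self_kin = 0.5 * (1.0 + phi[fp, mp])
            phi[i_rank, i_rank] = self_kin
            for j_rank in range(i_rank):
                val = 0.0
                if fp is not None:
                    val += 0.5 * phi[fp, j_rank]
                if mp is not None:
                    val += 0.5 * phi[mp, j_rank]
                phi[i_rank, j_rank] = phi[j_rank, i_rank] = val
        sel = np.array([rank[pos] for pos in members], dtype=np.intp)
        return phi[np.ix_(sel, sel)]

    def _topological(self, positions: Sequence[int]) -> list[int]:
        """Ancestors-first ordering of ``positions`` (parents precede children)."""
        pos_set = set(positions)
        seen: set[int] = set()
        order: list[int] = []
        for start in positions:
            if start in seen:
                continue
            stack = [(start, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    order.append(node)
                    continue
                if node in seen:
                    continue
                seen.add(node)
                stack.append((node, True))
                for pid in self._parent_ids(self.individuals[node].id):
                    p = self._index[pid]
                    if p in pos_set and p not in seen:
                        stack.append((p, False))
        return order


def read_pedigree(path) -> Pedigree:
    """Read a 5-column pedigree file (FAM, ID, FATHER, MOTHER, SEX).

    Whitespace- or comma-delimited; a header row is detected and skipped if
    its sex column is not a recognised code. Missing parents are encoded as
    ``0`` or an empty field. Compatible with the fixed columns of PLINK
    ``.fam`` files.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] < 5:
        raise PedigreeError(
            f"expected >= 5 columns (FAM ID FATHER MOTHER SEX), got {df.shape[1]}"
        )
    try:
        _norm_sex(df.iloc[0, 4])
    except PedigreeError:
        df = df.iloc[1:].reset_index(drop=True)  # header row
    if df.empty:
        return Pedigree([])
    return Pedigree.from_dataframe(df.iloc[:, :5])


def family_blocks(ped: Pedigree) -> list[np.ndarray]:
    """Positional index sets of the pedigree's independent blocks."""
    return ped.blocks


def kinship_matrix(ped: Pedigree, members: Iterable[int] | None = None) -> np.ndarray:
    """Kinship coefficients ``phi`` for ``members`` of ``ped`` (default: all)."""
    return ped.kinship(members)
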