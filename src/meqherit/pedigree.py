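"""Pedigree representation, validation, and the additive relationship matrix.

A pedigree is an acyclic graph of parent links over individuals; from it the
kinship coefficient phi(i, j) — the probability that an allele drawn at
random from i is identical by descent to one drawn from j — is computed by
the standard tabular (ancestors-first) recursion. The additive relationship
matrix A = 2*Phi is the genetic covariance structure of the polygenic model:
diagonal entries are 1 + F_i (F_i the inbreeding coefficient) and
off-diagonal entries are the expected fraction of shared additive variance
(0.5 parent-offspring or full sibs, 0.25 second-degree, 0.125 third-degree).

A missing parent is treated as a unique unrelated founder, the usual
convention; multiple disconnected families live in one Pedigree with
cross-family relatedness 0 by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Sex",
    "Individual",
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "kinship",
    "relative_degree",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or object."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


_SEX_CODES = {
    "1": Sex.male, "m": Sex.male, "male": Sex.male,
    "2": Sex.female, "f": Sex.female, "female": Sex.female,
    "0": Sex.unknown, "u": Sex.unknown, "unknown": Sex.unknown, "": Sex.unknown,
}

_MISSING = {"0", "", ".", "na", "none"}


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex


@dataclass
class Pedigree:
    """Validated collection of individuals with resolved parent links."""

    individuals: list[Individual]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {}
        for pos, ind in enumerate(self.individuals):
            if ind.id in self.index:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.index[ind.id] = pos
        self._validate()

    def _validate(self) -> None:
        by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            for pid, want in ((ind.father_id, Sex.male), (ind.mother_id, Sex.female)):
                if pid is None:
                    continue
                parent = by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{ind.id}: parent {pid!r} not present in pedigree"
                    )
                if parent.sex not in (want, Sex.unknown):
                    raise PedigreeError(
                        f"{ind.id}: parent {pid} recorded as "
                        f"{parent.sex.value}, expected {want.value}"
                    )
                if parent.family_id != ind.family_id:
                    raise PedigreeError(
                        f"{ind.id}: parent {pid} belongs to a different family"
                    )
            if ind.sex is Sex.unknown and not self.is_founder(ind.id):
                # unknown sex tolerated for founders only
                raise PedigreeError(f"{ind.id}: non-founder with unknown sex")
        self.topological_order()  # raises on cycles

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def is_founder(self, iid: str) -> bool:
        ind = self.individuals[self.index[iid]]
        return ind.father_id is None and ind.mother_id is None

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self.individuals if self.is_founder(i.id)]

    def topological_order(self) -> list[int]:
        """Positions sorted ancestors-first (Kahn); raises on a cycle."""
        n = len(self.individuals)
        children: dict[int, list[int]] = {i: [] for i in range(n)}
        indeg = [0] * n
        for pos, ind in enumerate(self.individuals):
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    children[self.index[pid]].append(pos)
                    indeg[pos] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        order: list[int] = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            cyclic = [self.individuals[i].id for i in range(n) if indeg[i] > 0]
            raise PedigreeError(
                f"pedigree contains a cycle involving: {', '.join(sorted(cyclic))}"
            )
        return order

    def subset(self, ids: Iterable[str]) -> "Pedigree":
        """Sub-pedigree on ``ids``; parents outside the subset become missing."""
        keep = set(ids)
        subs = []
        for ind in self.individuals:
            if ind.id not in keep:
                continue
            subs.append(
                Individual(
                    id=ind.id,
                    family_id=ind.family_id,
                    father_id=ind.father_id if ind.father_id in keep else None,
                    mother_id=ind.mother_id if ind.mother_id in keep else None,
                    sex=ind.sex,
                )
            )
        return Pedigree(subs)

    def family_of(self) -> dict[str, str]:
        return {ind.id: ind.family_id for ind in self.individuals}

    def write(self, path) -> None:
        """Write as a 5-column PED-prefix file (0 = missing parent)."""
        sex_out = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}
        with open(path, "w", encoding="utf-8") as fh:
            for ind in self.individuals:
                fh.write(
                    "\t".join(
                        [
                            ind.family_id,
                            ind.id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            sex_out[ind.sex],
                        ]
                    )
                    + "\n"
                )


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix 2*Phi over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise PedigreeError("relationship matrix shape does not match ids")

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def reorder(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {v: k for k, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    def to_triplet(self, path, tol: float = 0.0) -> None:
        """Matrix-market-style triplet file (row id, col id, value), lower triangle."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("%%relationship-matrix triplet\n")
            n = len(self.ids)
            for i in range(n):
                for j in range(i + 1):
                    v = self.values[i, j]
                    if abs(v) > tol or i == j:
                        fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{v:.10g}\n")


def read_pedigree(path) -> Pedigree:
    """Read a whitespace/tab-delimited 5-column file: family id father mother sex.

    '0' or blank marks a missing parent. Errors carry the offending line
    number.
    """
    individuals: list[Individual] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"line {lineno}: expected 5 columns "
                    "(family, id, father, mother, sex), got "
                    f"{len(parts)}"
                )
            fam, iid, fid, mid, sex_raw = parts[:5]
            if iid in seen:
                raise PedigreeError(f"line {lineno}: duplicate individual id {iid!r}")
            seen.add(iid)
            sex = _SEX_CODES.get(sex_raw.lower())
            if sex is None:
                raise PedigreeError(f"line {lineno}: unrecognized sex code {sex_raw!r}")
            individuals.append(
                Individual(
                    id=iid,
                    family_id=fam,
                    father_id=None if fid.lower() in _MISSING else fid,
                    mother_id=None if mid.lower() in _MISSING else mid,
                    sex=sex,
                )
            )
    try:
        return Pedigree(individuals)
    except PedigreeError as exc:
        raise PedigreeError(f"{path}: {exc}") from exc


def kinship(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix 2*Phi by the tabular recursion.

    Individuals are processed ancestors-first; for individual i with parents
    f, m: phi(i, i) = (1 + phi(f, m)) / 2 and phi(i, j) =
    (phi(f, j) + phi(m, j)) / 2 for any j already processed, with phi
    involving a missing parent equal to 0. Rows/columns are returned in the
    pedigree's own order.
    """
    n = len(ped)
    order = ped.topological_order()
    rank = {pos: k for k, pos in enumerate(order)}  # pedigree pos -> topo rank
    phi = np.zeros((n, n))
    for k, pos in enumerate(order):
        ind = ped.individuals[pos]
        f = ped.index.get(ind.father_id) if ind.father_id else None
        m = ped.index.get(ind.mother_id) if ind.mother_id else None
        fr = rank[f] if f is not None else None
        mr = rank[m] if m is not None else None
        if fr is None and mr is None:
            phi[k, k] = 0.5
            continue
        row = np.zeros(k)
        if fr is not None:
            row += 0.5 * phi[fr, :k]
        if mr is not None:
            row += 0.5 * phi[mr, :k]
        phi[k, :k] = row
        phi[:k, k] = row
        parents_phi = phi[fr, mr] if (fr is not None and mr is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + parents_phi)
    # back to pedigree order
    inv = np.empty(n, dtype=int)
    for k, pos in enumerate(order):
        inv[pos] = k
    A = 2.0 * phi[np.ix_(inv, inv)]
    return RelationshipMatrix(ped.ids, A)


_DEGREE_BANDS = (("first", 0.5), ("second", 0.25), ("third", 0.125))


def relative_degree(
    ped_or_matrix: Pedigree | RelationshipMatrix, a: str, b: str
) -> str:
    """Classify a pair as first/second/third-degree relatives or 'other'.

    Classification is on the outbred expectation: 2*phi of 0.5, 0.25 and
    0.125 map to first, second (half sibs, grandparent-grandchild,
    avuncular, double first cousins) and third degree (first cousins,
    great-avuncular); anything else — including the inbreeding-shifted
    values — is 'other'.
    """
    A = ped_or_matrix if isinstance(ped_or_matrix, RelationshipMatrix) else kinship(ped_or_matrix)
    for iid in (a, b):
        if iid not in A.ids:
            raise PedigreeError(f"unknown individual id {iid!r}")
    if a == b:
        raise PedigreeError("relative degree is defined for distinct individuals")
    v = A.loc(a, b)
    for name, expected in _DEGREE_BANDS:
        if abs(v - expected) < 1e-9:
            return name
    return "other"
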