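"""Pedigree structure, kinship/inbreeding coefficients, and gene-drop simulation.

A pedigree is a directed acyclic graph of individuals; founders have no
parents and are assumed unrelated and non-inbred.  The kinship coefficient
phi(i, j) is the probability that one allele sampled at random from i and
one from j are identical by descent; the inbreeding coefficient of an
individual is the kinship of its parents.  The additive relationship matrix
used by the association machinery is A = 2*Phi (diagonal 1 + f).

Kinship is computed by dynamic programming over a topological order
(parents before children), which is exact and O(n^2) — comfortable for
founder-population pedigrees of a few thousand individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "GeneDrop",
    "PedigreeError",
    "CycleError",
    "MissingParentError",
    "DuplicateIdError",
    "UnknownIdError",
    "validate_pedigree",
    "kinship_matrix",
    "inbreeding",
    "gene_drop",
    "gene_drop_replicates",
    "read_ped",
    "write_ped",
    "write_kinship_tsv",
]


class PedigreeError(ValueError):
    """Base class for structural pedigree problems."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""


class MissingParentError(PedigreeError):
    """A parent id is referenced but never defined."""


class DuplicateIdError(PedigreeError):
    """The same individual id appears more than once."""


class UnknownIdError(KeyError):
    """A queried id is not in the pedigree."""


MISSING = {None, "", "0", 0}

SEXES = {"M", "F", "U"}


def _norm_parent(value) -> str | None:
    if value in MISSING:
        return None
    return str(value)


def _norm_sex(value) -> str:
    s = str(value).strip().upper()
    if s in {"M", "MALE", "1"}:
        return "M"
    if s in {"F", "FEMALE", "2"}:
        return "F"
    return "U"


@dataclass(frozen=True)
class Individual:
    """One pedigree member. Founder iff both parent ids are ``None``."""

    id: str
    father: str | None
    mother: str | None
    sex: str = "U"

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None

    def __post_init__(self):
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"individual {self.id!r} has exactly one known parent; "
                "founders must have neither, non-founders both"
            )
        if self.sex not in SEXES:
            raise PedigreeError(f"individual {self.id!r} has invalid sex {self.sex!r}")


class Pedigree:
    """Validated, topologically sorted collection of :class:`Individual`.

    ``ped.order`` lists ids with every parent before its children;
    ``ped.generation[i]`` is 0 for founders and 1 + max(parent generations)
    otherwise, so ``ped.depth`` counts generations.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in members:
                raise DuplicateIdError(f"duplicated id {ind.id!r}")
            members[ind.id] = ind
        for ind in members.values():
            for pid in (ind.father, ind.mother):
                if pid is not None and pid not in members:
                    raise MissingParentError(
                        f"individual {ind.id!r} references missing parent {pid!r}"
                    )
        self._members = members
        self.order = self._toposort()
        self.index = {iid: k for k, iid in enumerate(self.order)}
        self.generation = {}
        for iid in self.order:
            ind = members[iid]
            if ind.is_founder:
                self.generation[iid] = 0
            else:
                self.generation[iid] = 1 + max(
                    self.generation[ind.father], self.generation[ind.mother]
                )

    def _toposort(self) -> list[str]:
        # Kahn's algorithm; leftover nodes imply a cycle.
        children: dict[str, list[str]] = {iid: [] for iid in self._members}
        pending = {}
        for ind in self._members.values():
            parents = {p for p in (ind.father, ind.mother) if p is not None}
            pending[ind.id] = len(parents)
            for p in parents:
                children[p].append(ind.id)
        queue = sorted(iid for iid, k in pending.items() if k == 0)
        order: list[str] = []
        while queue:
            iid = queue.pop(0)
            order.append(iid)
            ready = []
            for c in children[iid]:
                pending[c] -= 1
                if pending[c] == 0:
                    ready.append(c)
            queue.extend(sorted(ready))
        if len(order) != len(self._members):
            stuck = sorted(set(self._members) - set(order))
            raise CycleError(f"pedigree contains a cycle involving {stuck[:5]}")
        return order

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._members

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._members[iid]
        except KeyError:
            raise UnknownIdError(iid) from None

    def __iter__(self):
        return (self._members[iid] for iid in self.order)

    @property
    def founders(self) -> list[str]:
        return [iid for iid in self.order if self._members[iid].is_founder]

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def depth(self) -> int:
        """Number of generations (founder-only pedigree has depth 1)."""
        return 1 + max(self.generation.values()) if self._members else 0


def validate_pedigree(raw_records: Iterable[Sequence]) -> Pedigree:
    """Build a :class:`Pedigree` from (id, father, mother, sex) records.

    Raises :class:`DuplicateIdError`, :class:`MissingParentError` or
    :class:`CycleError` on the corresponding structural defect.
    """
    inds = [
        Individual(str(r[0]), _norm_parent(r[1]), _norm_parent(r[2]),
                   _norm_sex(r[3]) if len(r) > 3 else "U")
        for r in raw_records
    ]
    return Pedigree(inds)


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients for every individual in a pedigree."""

    ids: list[str]
    phi: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def get(self, i: str, j: str) -> float:
        try:
            return float(self.phi[self._index[i], self._index[j]])
        except KeyError as e:
            raise UnknownIdError(e.args[0]) from None

    def additive(self) -> np.ndarray:
        """Additive relationship matrix A = 2*Phi (diagonal 1 + f)."""
        return 2.0 * self.phi

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self._index[i] for i in ids]
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)])


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Recursive kinship over the topological order.

    phi(i,i) = (1 + phi(father_i, mother_i)) / 2, phi = 1/2 for founders;
    phi(i,j) = (phi(father_i, j) + phi(mother_i, j)) / 2 for j processed
    before i (j can never be a descendant of i in topological order).
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for k, iid in enumerate(ped.order):
        ind = ped[iid]
        if ind.is_founder:
            phi[k, k] = 0.5
            # founders unrelated to everything already processed
        else:
            fi, mi = ped.index[ind.father], ped.index[ind.mother]
            phi[k, k] = 0.5 * (1.0 + phi[fi, mi])
            if k:
                row = 0.5 * (phi[fi, :k] + phi[mi, :k])
                phi[k, :k] = row
                phi[:k, k] = row
    return KinshipMatrix(list(ped.order), phi)


def inbreeding(ped: Pedigree, iid: str, kin: KinshipMatrix | None = None) -> float:
    """Inbreeding coefficient f = kinship of the parents; 0 for founders."""
    ind = ped[iid]
    if ind.is_founder:
        return 0.0
    if kin is None:
        kin = kinship_matrix(ped)
    return kin.get(ind.father, ind.mother)


@dataclass
class GeneDrop:
    """One Mendelian gene-drop realization at a biallelic autosomal locus.

    ``genotypes[id] = (paternal_allele, maternal_allele)`` with alleles in
    {0, 1}; founder alleles are i.i.d. Bernoulli(founder_allele_freq).
    """

    founder_allele_freq: float
    seed: int
    genotypes: dict[str, tuple[int, int]]

    def dosage(self, iid: str) -> int:
        a, b = self.genotypes[iid]
        return a + b


def gene_drop(ped: Pedigree, p: float, seed: int) -> GeneDrop:
    """Drop alleles with frequency ``p`` through the pedigree, reproducibly."""
    reps = gene_drop_replicates(ped, p, 1, seed)
    geno = {iid: (int(reps[0, k, 0]), int(reps[0, k, 1]))
            for k, iid in enumerate(ped.order)}
    return GeneDrop(p, seed, geno)


def gene_drop_replicates(ped: Pedigree, p: float, n_rep: int, seed: int) -> np.ndarray:
    """Vectorized gene drop: array (n_rep, n_individuals, 2) of alleles.

    Axis 2 is (paternal, maternal).  Individuals follow ``ped.order``.
    Used both as input generator and as the Monte-Carlo IBD oracle for
    kinship (sharing probability of single sampled alleles -> phi).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"founder allele frequency must be in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    n = len(ped)
    alleles = np.empty((n_rep, n, 2), dtype=np.int8)
    for k, iid in enumerate(ped.order):
        ind = ped[iid]
        if ind.is_founder:
            alleles[:, k, :] = rng.random((n_rep, 2)) < p
        else:
            fi, mi = ped.index[ind.father], ped.index[ind.mother]
            pick = rng.integers(0, 2, size=(n_rep, 2))
            rows = np.arange(n_rep)
            alleles[:, k, 0] = alleles[rows, fi, pick[:, 0]]
            alleles[:, k, 1] = alleles[rows, mi, pick[:, 1]]
    return alleles


# ---------------------------------------------------------------------------
# I/O: whitespace/CSV PED dialect `id father mother sex`, PLINK .fam accepted.

def read_ped(path: str | Path) -> Pedigree:
    """Read a PED-like file.

    Accepted layouts per line (comma or whitespace separated, ``#`` comments):
    4+ columns ``id father mother sex`` or 6 columns PLINK .fam
    ``fid iid father mother sex pheno``.  ``0`` or empty means missing parent.
    """
    records = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in (line.split(",") if "," in line else line.split())]
        if len(fields) == 6:  # PLINK .fam
            _, iid, fa, mo, sex, _ = fields
        elif len(fields) >= 4:
            iid, fa, mo, sex = fields[:4]
        elif len(fields) == 3:
            iid, fa, mo = fields
            sex = "U"
        else:
            raise PedigreeError(f"cannot parse pedigree line: {line!r}")
        records.append((iid, fa, mo, sex))
    return validate_pedigree(records)


def write_ped(ped: Pedigree, path: str | Path, header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("# id father mother sex")
    for ind in ped:
        lines.append(f"{ind.id} {ind.father or 0} {ind.mother or 0} {ind.sex}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_kinship_tsv(kin: KinshipMatrix, path: str | Path, full: bool = False) -> None:
    """Write kinship as TSV: header row of ids, then lower triangle (or full)."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(kin.ids) + "\n")
        for k, iid in enumerate(kin.ids):
            stop = len(kin.ids) if full else k + 1
            vals = "\t".join(f"{kin.phi[k, j]:.8g}" for j in range(stop))
            fh.write(f"{iid}\t{vals}\n")
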