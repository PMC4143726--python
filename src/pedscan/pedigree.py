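"""Pedigree data model, validation, kinship computation, and ped/fam file I/O.

A :class:`Pedigree` is a validated, topologically ordered family structure
(founders first).  The additive genetic covariance used throughout the
package is twice the kinship matrix, ``2 * Phi``, where ``phi_ij`` is the
probability that an allele drawn at random from individual *i* is identical
by descent (IBD) to one drawn from *j*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

SEX_MALE = "male"
SEX_FEMALE = "female"
SEX_UNKNOWN = "unknown"

_SEX_CODES = {"1": SEX_MALE, "2": SEX_FEMALE, "0": SEX_UNKNOWN}
_SEX_TO_CODE = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Structural error in a pedigree definition (cycles, bad parent links...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` / ``mother_id`` are ``None`` for founders; an individual
    has either both parents known or neither.
    """

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id!r} in family {self.family_id!r} "
                "has only one parent specified; pedigrees require both or neither"
            )
        if self.sex not in (SEX_MALE, SEX_FEMALE, SEX_UNKNOWN):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.individual_id!r}")
        if self.father_id == self.individual_id or self.mother_id == self.individual_id:
            raise PedigreeError(
                f"individual {self.individual_id!r} lists itself as a parent"
            )


class Pedigree:
    """A single family: validated members in deterministic topological order.

    Members are stored founders-first; ties are broken lexicographically on
    ``individual_id`` so that all derived outputs are byte-stable regardless
    of input order.
    """

    def __init__(self, members: Iterable[Individual], family_id: str | None = None):
        members = list(members)
        if not members:
            raise PedigreeError("empty pedigree")
        fam_ids = {m.family_id for m in members}
        if len(fam_ids) != 1:
            raise PedigreeError(f"mixed family ids in one pedigree: {sorted(fam_ids)}")
        self.family_id: str = family_id or members[0].family_id

        by_id: dict[str, Individual] = {}
        for m in members:
            if m.individual_id in by_id:
                raise PedigreeError(
                    f"duplicate individual {m.individual_id!r} in family {self.family_id!r}"
                )
            by_id[m.individual_id] = m

        for m in members:
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is None:
                    continue
                if pid not in by_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {m.individual_id!r} is not a member "
                        f"of family {self.family_id!r}"
                    )
                parent = by_id[pid]
                want = SEX_MALE if role == "father" else SEX_FEMALE
                if parent.sex == SEX_UNKNOWN:
                    if not parent.is_founder:
                        raise PedigreeError(
                            f"non-founder parent {pid!r} has unknown sex"
                        )
                elif parent.sex != want:
                    raise PedigreeError(
                        f"{role} {pid!r} of {m.individual_id!r} has sex "
                        f"{parent.sex!r}, inconsistent with parental role"
                    )

        self.members: tuple[Individual, ...] = tuple(self._topo_sort(by_id))
        self._index: dict[str, int] = {
            m.individual_id: i for i, m in enumerate(self.members)
        }
        if not any(m.is_founder for m in self.members):
            raise PedigreeError(f"family {self.family_id!r} has no founder")

    @staticmethod
    def _topo_sort(by_id: Mapping[str, Individual]) -> list[Individual]:
        # Kahn's algorithm with a lexicographically ordered frontier; a cycle
        # leaves unprocessed members behind.
        children: dict[str, list[str]] = {i: [] for i in by_id}
        n_parents: dict[str, int] = {}
        for m in by_id.values():
            n_parents[m.individual_id] = 0 if m.is_founder else 2
            if not m.is_founder:
                children[m.father_id].append(m.individual_id)
                children[m.mother_id].append(m.individual_id)
        frontier = sorted(i for i, n in n_parents.items() if n == 0)
        out: list[Individual] = []
        while frontier:
            frontier.sort()
            cur = frontier.pop(0)
            out.append(by_id[cur])
            for c in children[cur]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    frontier.append(c)
        if len(out) != len(by_id):
            cyclic = sorted(set(by_id) - {m.individual_id for m in out})
            raise PedigreeError(
                f"cyclic parentage in family {by_id[cyclic[0]].family_id!r} "
                f"involving {cyclic}"
            )
        return out

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __getitem__(self, individual_id: str) -> Individual:
        return self.members[self._index[individual_id]]

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.individual_id for m in self.members)

    @property
    def founders(self) -> tuple[Individual, ...]:
        return tuple(m for m in self.members if m.is_founder)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Pedigree({self.family_id!r}, n={len(self)}, "
            f"founders={len(self.founders)})"
        )


@dataclass
class KinshipMatrix:
    """Kinship coefficients ``phi_ij`` for one pedigree.

    ``values[i, j]`` is the kinship between members ``ids[i]`` and ``ids[j]``;
    the diagonal is ``(1 + f_i) / 2`` with ``f_i`` the inbreeding coefficient.
    ``matrix2`` (i.e. ``2 * Phi``) is the additive-genetic structuring matrix.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    family_id: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match ids")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def phi(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def matrix2(self) -> np.ndarray:
        """Twice the kinship matrix (additive genetic covariance structure)."""
        return 2.0 * self.values

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self._index[i] for i in ids]
        return KinshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)], self.family_id)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the standard tabular recursion over topological order.

    For non-founder *j* with parents *f, m* (processed earlier) and any
    earlier member *i*:  ``phi_ij = (phi_if + phi_im) / 2`` and
    ``phi_jj = (1 + phi_fm) / 2``.  Founders are unrelated and non-inbred.
    The recursion is exact for arbitrarily looped (inbred) pedigrees.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for j, m in enumerate(ped.members):
        if m.is_founder:
            phi[j, j] = 0.5
        else:
            fi = ped.index_of(m.father_id)
            mi = ped.index_of(m.mother_id)
            phi[j, j] = 0.5 * (1.0 + phi[fi, mi])
            row = 0.5 * (phi[:j, fi] + phi[:j, mi])
            phi[:j, j] = row
            phi[j, :j] = row
    return KinshipMatrix(ped.ids, phi, ped.family_id)


def read_pedigree(
    path: str | Path,
    dialect: str = "linkage_ped",
    strict: bool = False,
) -> list[Pedigree]:
    """Read a LINKAGE-style ped or PLINK .fam file into one Pedigree per family.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown); trailing columns (phenotype, genotypes) are ignored.  The
    missing-parent code is ``"0"``.  Individuals referenced only as parents
    are auto-added as unknown-sex founders with a logged warning, unless
    ``strict`` is true, in which case they raise :class:`PedigreeError`.
    """
    if dialect not in ("linkage_ped", "plink_fam"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected at least 5 columns, got {len(fields)}"
                )
            rows.append((lineno, fields[:5]))

    families: dict[str, list[Individual]] = {}
    seen: dict[str, set[str]] = {}
    parent_refs: dict[str, dict[str, str]] = {}  # fam -> parent id -> role
    for lineno, (fam, ind, fat, mot, sex_code) in ((ln, f) for ln, f in rows):
        if sex_code not in _SEX_CODES:
            raise PedigreeError(f"{path}:{lineno}: invalid sex code {sex_code!r}")
        try:
            member = Individual(
                individual_id=ind,
                family_id=fam,
                father_id=None if fat == MISSING_PARENT else fat,
                mother_id=None if mot == MISSING_PARENT else mot,
                sex=_SEX_CODES[sex_code],
            )
        except PedigreeError as exc:
            raise PedigreeError(f"{path}:{lineno}: {exc}") from exc
        if ind in seen.setdefault(fam, set()):
            raise PedigreeError(
                f"{path}:{lineno}: duplicate individual {ind!r} in family {fam!r}"
            )
        seen[fam].add(ind)
        families.setdefault(fam, []).append(member)
        for pid, role in ((member.father_id, "father"), (member.mother_id, "mother")):
            if pid is not None:
                parent_refs.setdefault(fam, {})[pid] = role

    for fam, refs in parent_refs.items():
        missing = sorted(set(refs) - seen[fam])
        if missing:
            if strict:
                raise PedigreeError(
                    f"{path}: family {fam!r} references absent parents {missing}"
                )
            logger.warning(
                "family %s: auto-adding %d parent(s) absent from the file "
                "as unknown-sex founders: %s",
                fam, len(missing), missing,
            )
            for pid in missing:
                families[fam].append(
                    Individual(pid, fam, None, None, SEX_UNKNOWN)
                )

    return [Pedigree(members) for _, members in sorted(families.items())]


def write_pedigree(peds: Iterable[Pedigree], path: str | Path) -> None:
    """Write pedigrees as a LINKAGE-style ped file (phenotype column 0)."""
    with Path(path).open("w") as fh:
        for ped in peds:
            for m in ped.members:
                fh.write(
                    f"{m.family_id}\t{m.individual_id}\t"
                    f"{m.father_id or MISSING_PARENT}\t{m.mother_id or MISSING_PARENT}\t"
                    f"{_SEX_TO_CODE[m.sex]}\t0\n"
                )
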