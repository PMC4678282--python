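"""Pedigrees and relatedness matrices.

Families are parsed from PLINK-style ``.fam`` text (FID IID FATHER MOTHER SEX,
with optional household and monozygotic-twin-tag columns) and turned into the
per-family kinship matrix Phi, fraternity matrix Delta and shared-environment
indicator Gamma that parameterize the polygenic covariance model

    cov(y_j, y_k) = 2 * sigma_a^2 * Phi_jk + sigma_d^2 * Delta_jk
                    + sigma_e^2 * Gamma_jk.

Phi(j, k) is the probability that one allele drawn at random from each of j
and k is identical by descent; Delta(j, k) is the probability that j and k
share both alleles identical by descent at a locus.  Both are computed from
parent links under random mating: Phi by the standard recursive algorithm over
a founder-first ordering, Delta by the condensed-identity formula for
non-inbred pairs.  Monozygotic twins, which parent links cannot express, are
supported through an explicit twin-group tag and treated as genetically
identical (Phi = 1/2, Delta = 1 within a group).

The full-sample relatedness is block diagonal by family and is never
materialized densely; :class:`RelatednessBlocks` keeps one small matrix set
per family, with cached inverses and size-grouped stacks for vectorized
likelihood evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Family",
    "Pedigree",
    "RelatednessBlocks",
    "PedigreeError",
    "PedigreeParseError",
    "read_pedigree",
    "write_pedigree",
    "kinship_matrix",
    "fraternity_matrix",
    "environment_matrix",
    "relatedness_table",
]

MALE = "male"
FEMALE = "female"


class PedigreeError(ValueError):
    """A structurally invalid pedigree (cycles, sex conflicts, bad links)."""


class PedigreeParseError(PedigreeError):
    """A malformed pedigree file; carries the offending line number."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders.  ``mz_twin_group``
    tags monozygotic twins: members of a family sharing a tag are treated as
    genetically identical.
    """

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = MALE
    household: str | None = None
    mz_twin_group: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise PedigreeError(
                f"individual {self.individual_id!r}: sex must be "
                f"{MALE!r} or {FEMALE!r}, got {self.sex!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Family:
    """An ordered collection of individuals sharing a family id."""

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def _by_id(self) -> dict[str, Individual]:
        return {m.individual_id: m for m in self.members}

    def validate(self) -> None:
        by_id = self._by_id()
        for m in self.members:
            for pid, want_sex, label in (
                (m.father_id, MALE, "father"),
                (m.mother_id, FEMALE, "mother"),
            ):
                if pid is None:
                    continue
                parent = by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"family {self.family_id!r}: {label} {pid!r} of "
                        f"{m.individual_id!r} is not a member of the family"
                    )
                if parent.sex != want_sex:
                    raise PedigreeError(
                        f"family {self.family_id!r}: {label} {pid!r} of "
                        f"{m.individual_id!r} is recorded as {parent.sex}"
                    )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[Individual]:
        """Members ordered founders-first (parents before children)."""
        by_id = self._by_id()
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(m: Individual) -> None:
            st = state.get(m.individual_id)
            if st == 1:
                return
            if st == 0:
                raise PedigreeError(
                    f"family {self.family_id!r}: cyclic ancestry involving "
                    f"{m.individual_id!r}"
                )
            state[m.individual_id] = 0
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid in by_id:
                    visit(by_id[pid])
            state[m.individual_id] = 1
            order.append(m)

        for m in self.members:
            visit(m)
        return order


@dataclass
class Pedigree:
    """An ordered collection of families; singletons are size-1 families."""

    families: list[Family] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return sum(len(f) for f in self.families)

    def __iter__(self):
        return iter(self.families)

    @property
    def individual_ids(self) -> list[str]:
        return [i for f in self.families for i in f.member_ids]

    def individuals(self) -> Iterable[Individual]:
        for f in self.families:
            yield from f.members

    def validate(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            for m in fam.members:
                if m.individual_id in seen:
                    raise PedigreeError(
                        f"duplicate individual id {m.individual_id!r}"
                    )
                if m.family_id != fam.family_id:
                    raise PedigreeError(
                        f"individual {m.individual_id!r} carries family id "
                        f"{m.family_id!r} inside family {fam.family_id!r}"
                    )
                seen.add(m.individual_id)
            fam.validate()

    def sex_series(self) -> pd.Series:
        return pd.Series(
            {m.individual_id: m.sex for m in self.individuals()}, name="sex"
        )

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "Pedigree":
        fams: dict[str, Family] = {}
        order: list[str] = []
        for ind in individuals:
            if ind.family_id not in fams:
                fams[ind.family_id] = Family(ind.family_id)
                order.append(ind.family_id)
            fams[ind.family_id].members.append(ind)
        return cls([fams[fid] for fid in order])


# ---------------------------------------------------------------------------
# .fam I/O


def _parse_sex(token: str, lineno: int) -> str:
    if token == "1":
        return MALE
    if token == "2":
        return FEMALE
    raise PedigreeParseError(
        f"line {lineno}: sex must be 1 (male) or 2 (female), got {token!r}"
    )


def read_pedigree(path, dialect: str = "fam") -> Pedigree:
    """Read a pedigree from PLINK-style ``.fam`` text.

    Columns: family id, individual id, father id, mother id, sex (1=male,
    2=female); a parent id of ``0`` means founder.  Optional 6th column is a
    household id and optional 7th a monozygotic-twin tag (``0`` = absent for
    both).  Whitespace- or tab-delimited.
    """
    if dialect != "fam":
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    individuals: list[Individual] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 5:
                raise PedigreeParseError(
                    f"line {lineno}: expected at least 5 columns "
                    f"(FID IID FATHER MOTHER SEX), got {len(tok)}"
                )
            fid, iid, fa, mo, sex = tok[:5]
            household = tok[5] if len(tok) > 5 and tok[5] != "0" else None
            twin = tok[6] if len(tok) > 6 and tok[6] != "0" else None
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=_parse_sex(sex, lineno),
                    household=household,
                    mz_twin_group=twin,
                )
            )
    return Pedigree.from_individuals(individuals)


def write_pedigree(pedigree: Pedigree, path) -> None:
    """Write the ``.fam`` dialect accepted by :func:`read_pedigree`."""
    with open(path, "wt", encoding="utf-8") as fh:
        for m in pedigree.individuals():
            cols = [
                m.family_id,
                m.individual_id,
                m.father_id or "0",
                m.mother_id or "0",
                "1" if m.sex == MALE else "2",
            ]
            if m.household is not None or m.mz_twin_group is not None:
                cols.append(m.household or "0")
            if m.mz_twin_group is not None:
                cols.append(m.mz_twin_group)
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Relatedness matrices


def _genotype_rep(family: Family) -> dict[str, str]:
    """Map each member id to its genotype representative (first-listed MZ twin)."""
    rep: dict[str, str] = {}
    first_of_group: dict[str, str] = {}
    for m in family.members:
        if m.mz_twin_group is None:
            rep[m.individual_id] = m.individual_id
        else:
            key = first_of_group.setdefault(m.mz_twin_group, m.individual_id)
            rep[m.individual_id] = key
    return rep


def _kinship_dict(family: Family) -> tuple[dict[tuple[str, str], float], dict[str, str]]:
    """Kinship over genotype representatives, keyed by ordered id pairs."""
    rep = _genotype_rep(family)
    by_id = family._by_id()
    order = [m.individual_id for m in family.topological_order()]
    # genotype nodes in topological order, deduplicated through rep
    nodes: list[str] = []
    for iid in order:
        r = rep[iid]
        if r not in nodes:
            nodes.append(r)

    def parents(node: str) -> tuple[str | None, str | None]:
        m = by_id[node]
        fa = rep.get(m.father_id) if m.father_id in by_id else None
        mo = rep.get(m.mother_id) if m.mother_id in by_id else None
        return fa, mo

    phi: dict[tuple[str, str], float] = {}

    def get(a: str, b: str) -> float:
        return phi.get((a, b), phi.get((b, a), 0.0))

    for idx, a in enumerate(nodes):
        fa, mo = parents(a)
        for b in nodes[:idx]:
            if fa is None and mo is None:
                val = 0.0
            else:
                val = 0.5 * (
                    (get(fa, b) if fa is not None else 0.0)
                    + (get(mo, b) if mo is not None else 0.0)
                )
            phi[(a, b)] = val
        f_am = get(fa, mo) if (fa is not None and mo is not None) else 0.0
        phi[(a, a)] = 0.5 * (1.0 + f_am)
    return phi, rep


def kinship_matrix(family: Family) -> np.ndarray:
    """Kinship matrix Phi of a family, in family member order.

    Founders have self-kinship 1/2 and pairwise kinship 0; a non-founder's
    kinship with an earlier member averages its parents' values, and its
    self-kinship is (1 + Phi(father, mother)) / 2.  A single missing parent is
    treated as a unique unrelated founder.  Monozygotic twins share a genotype
    node, so Phi = 1/2 within a twin group.
    """
    phi, rep = _kinship_dict(family)

    def get(a: str, b: str) -> float:
        return phi.get((a, b), phi.get((b, a), 0.0))

    ids = family.member_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids[: i + 1]):
            ra, rb = rep[a], rep[b]
            out[i, j] = out[j, i] = get(ra, rb)
    return out


def fraternity_matrix(family: Family, phi: np.ndarray | None = None) -> np.ndarray:
    """Fraternity matrix Delta (probability of sharing both alleles IBD).

    For non-inbred j != k with parent pairs (fj, mj) and (fk, mk),

        Delta(j, k) = Phi(fj, fk) Phi(mj, mk) + Phi(fj, mk) Phi(mj, fk),

    with terms through a missing parent equal to zero; founder pairs have
    Delta = 0, the diagonal is 1 and monozygotic co-twins have Delta = 1.
    The formula is exact only without inbreeding; inbred parent pairs trigger
    a warning.
    """
    kin, rep = _kinship_dict(family)

    def get(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        return kin.get((a, b), kin.get((b, a), 0.0))

    by_id = family._by_id()

    def parents(iid: str) -> tuple[str | None, str | None]:
        m = by_id[rep[iid]]
        fa = rep.get(m.father_id) if m.father_id in by_id else None
        mo = rep.get(m.mother_id) if m.mother_id in by_id else None
        return fa, mo

    for m in family.members:
        fa, mo = parents(m.individual_id)
        if get(fa, mo) > 0:
            warnings.warn(
                f"family {family.family_id!r}: inbred parent pair of "
                f"{m.individual_id!r}; fraternity values use the non-inbred "
                "formula and are approximate",
                stacklevel=2,
            )
            break

    ids = family.member_ids
    n = len(ids)
    out = np.eye(n)
    for i, a in enumerate(ids):
        fa_a, mo_a = parents(a)
        for j in range(i):
            b = ids[j]
            if rep[a] == rep[b]:  # MZ co-twins
                out[i, j] = out[j, i] = 1.0
                continue
            fa_b, mo_b = parents(b)
            val = get(fa_a, fa_b) * get(mo_a, mo_b) + get(fa_a, mo_b) * get(
                mo_a, fa_b
            )
            out[i, j] = out[j, i] = val
    return out


def environment_matrix(
    family: Family, households: Mapping[str, str] | None = None
) -> np.ndarray:
    """Shared-environment indicator Gamma: 1 when two members cohabit.

    Household membership comes from ``households`` (id -> household key) or
    from the individuals' ``household`` attribute; with neither, Gamma is the
    identity (members treated as living apart).
    """
    ids = family.member_ids
    n = len(ids)
    if households is None:
        keys = [m.household for m in family.members]
    else:
        keys = [households.get(i) for i in ids]
    out = np.eye(n)
    for i in range(n):
        for j in range(i):
            if keys[i] is not None and keys[i] == keys[j]:
                out[i, j] = out[j, i] = 1.0
    return out


# ---------------------------------------------------------------------------
# Blocks


@dataclass
class FamilyBlock:
    """Relatedness matrices of one family, restricted to observed members."""

    family_id: str
    ids: list[str]
    phi: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    phi_inv: np.ndarray
    male: np.ndarray  # boolean mask, aligned with ids

    @property
    def size(self) -> int:
        return len(self.ids)


class RelatednessBlocks:
    """Per-family Phi / Delta / Gamma blocks plus cached Phi inverses.

    ``ids`` gives the concatenated subject order used by every flat array the
    estimators exchange with these blocks.  ``groups()`` returns the families
    stacked by size for batched linear algebra.
    """

    def __init__(self, blocks: list[FamilyBlock]):
        self.blocks = blocks
        self.ids: list[str] = [i for b in blocks for i in b.ids]
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        self._groups: list[dict] | None = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_families(self) -> int:
        return len(self.blocks)

    @classmethod
    def from_pedigree(
        cls,
        pedigree: Pedigree,
        ids: Sequence[str] | None = None,
        households: Mapping[str, str] | None = None,
    ) -> "RelatednessBlocks":
        """Build blocks, optionally restricted to a subset of subjects.

        Matrices are computed on the whole family and then sliced to the
        observed members (the marginal of a multivariate normal is the
        corresponding submatrix), so relatives outside the subset still shape
        the relatedness of those inside it.
        """
        keep = None if ids is None else set(ids)
        blocks: list[FamilyBlock] = []
        for fam in pedigree.families:
            sel = [
                k
                for k, m in enumerate(fam.members)
                if keep is None or m.individual_id in keep
            ]
            if not sel:
                continue
            phi = kinship_matrix(fam)
            delta = fraternity_matrix(fam, phi)
            gamma = environment_matrix(fam, households)
            idx = np.asarray(sel)
            phi = phi[np.ix_(idx, idx)]
            delta = delta[np.ix_(idx, idx)]
            gamma = gamma[np.ix_(idx, idx)]
            try:
                phi_inv = np.linalg.inv(phi)
            except np.linalg.LinAlgError:
                # monozygotic twins duplicate kinship rows; the pseudo-inverse
                # keeps the quadratic forms well defined on the attained span
                warnings.warn(
                    f"family {fam.family_id!r}: singular kinship matrix "
                    "(monozygotic twins); using the pseudo-inverse"
                )
                phi_inv = np.linalg.pinv(phi)
            blocks.append(
                FamilyBlock(
                    family_id=fam.family_id,
                    ids=[fam.members[k].individual_id for k in sel],
                    phi=phi,
                    delta=delta,
                    gamma=gamma,
                    phi_inv=phi_inv,
                    male=np.asarray(
                        [fam.members[k].sex == MALE for k in sel], dtype=bool
                    ),
                )
            )
        if keep is not None:
            missing = keep - {i for b in blocks for i in b.ids}
            if missing:
                raise PedigreeError(
                    "subjects absent from the pedigree: "
                    + ", ".join(sorted(missing)[:10])
                )
        return cls(blocks)

    def align(self, values: pd.Series) -> np.ndarray:
        """Reindex an id-keyed series into the blocks' flat subject order."""
        out = values.reindex(self.ids)
        if out.isna().any():
            missing = list(out.index[out.isna()])[:10]
            raise KeyError(f"values missing for subjects: {missing}")
        return out.to_numpy(dtype=float)

    def male_flat(self) -> np.ndarray:
        return np.concatenate([b.male for b in self.blocks])

    def groups(self) -> list[dict]:
        """Families stacked by size: arrays phi/delta/gamma (m, s, s), male
        (m, s) and idx (m, s) indexing into the flat subject order."""
        if self._groups is None:
            by_size: dict[int, list[FamilyBlock]] = {}
            offsets: dict[str, int] = {}
            off = 0
            for b in self.blocks:
                by_size.setdefault(b.size, []).append(b)
                offsets[b.family_id] = off
                off += b.size
            groups = []
            for s in sorted(by_size):
                bs = by_size[s]
                groups.append(
                    {
                        "size": s,
                        "phi": np.stack([b.phi for b in bs]),
                        "delta": np.stack([b.delta for b in bs]),
                        "gamma": np.stack([b.gamma for b in bs]),
                        "phi_inv": np.stack([b.phi_inv for b in bs]),
                        "male": np.stack([b.male for b in bs]),
                        "idx": np.stack(
                            [
                                np.arange(offsets[b.family_id], offsets[b.family_id] + s)
                                for b in bs
                            ]
                        ),
                    }
                )
            self._groups = groups
        return self._groups


def relatedness_table(pedigree: Pedigree) -> pd.DataFrame:
    """Long-format pairwise relatedness: columns id1, id2, phi, delta.

    One row per unordered within-family pair, including the diagonal.
    """
    rows = []
    for fam in pedigree.families:
        phi = kinship_matrix(fam)
        delta = fraternity_matrix(fam, phi)
        ids = fam.member_ids
        for i in range(len(ids)):
            for j in range(i + 1):
                rows.append((ids[i], ids[j], phi[i, j], delta[i, j]))
    return pd.DataFrame(rows, columns=["id1", "id2", "phi", "delta"])
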