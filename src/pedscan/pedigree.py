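"""Pedigree parsing and the additive genetic relationship matrix.

The additive (numerator) relationship matrix A — twice the kinship
coefficient — is the covariance kernel of the family random effect used by
every mixed model in the pipeline.  It is built with the classic tabular
method: individuals are processed parents-before-children and

    A[i,i] = 1 + 0.5 * A[father(i), mother(i)]
    A[i,j] = 0.5 * (A[j, father(i)] + A[j, mother(i)])    (j processed before i)

with missing parents contributing zero (treated as unrelated founders).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "Pedigree",
    "RelationshipMatrix",
    "read_pedigree",
    "additive_relationship",
]

MISSING = "0"

Sex = Literal["male", "female", "unknown"]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
              "m": "male", "f": "female",
              "male": "male", "female": "female", "unknown": "unknown"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, orphans)."""


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex


@dataclass
class Pedigree:
    """A validated set of pedigree records.

    Invariants (enforced on construction): individual ids are unique, every
    non-missing parent id resolves to a record, and no individual is its own
    ancestor.
    """

    records: list[PedigreeRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r.individual_id for r in self.records]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise PedigreeError(f"duplicate individual_id: {dup!r}")
        known = set(ids)
        for r in self.records:
            for p in (r.father_id, r.mother_id):
                if p is not None and p not in known:
                    raise PedigreeError(
                        f"parent {p!r} of {r.individual_id!r} is not in the pedigree"
                    )
        self._index = {iid: k for k, iid in enumerate(ids)}
        self.topological_order()  # raises on cycles

    # -- basic accessors ---------------------------------------------------
    @property
    def individual_ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def record(self, individual_id: str) -> PedigreeRecord:
        return self.records[self._index[individual_id]]

    def founders(self) -> list[str]:
        return [r.individual_id for r in self.records
                if r.father_id is None and r.mother_id is None]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for r in self.records:
            fams.setdefault(r.family_id, []).append(r.individual_id)
        return fams

    def topological_order(self) -> list[str]:
        """Individual ids ordered so parents precede children.

        Kahn's algorithm on the parent->child graph; a leftover node set
        means a cycle (someone is their own ancestor).
        """
        children: dict[str, list[str]] = {iid: [] for iid in self._index}
        indeg = {iid: 0 for iid in self._index}
        for r in self.records:
            for p in (r.father_id, r.mother_id):
                if p is not None:
                    children[p].append(r.individual_id)
                    indeg[r.individual_id] += 1
        queue = [iid for iid in self.individual_ids if indeg[iid] == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for c in children[iid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != self.n:
            cyclic = sorted(iid for iid, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle involving: {cyclic}")
        return order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": [r.family_id for r in self.records],
                "individual_id": [r.individual_id for r in self.records],
                "father_id": [r.father_id or MISSING for r in self.records],
                "mother_id": [r.mother_id or MISSING for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )

    def write(self, path: str | Path) -> None:
        """Write PLINK-.fam-style five columns (sex coded 1/2/0)."""
        df = self.to_frame()
        df["sex"] = df["sex"].map({"male": "1", "female": "2", "unknown": "0"})
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix with its sample order.

    values[i, j] is the expected additive genetic covariance between
    individuals i and j in units of the additive variance; the diagonal is
    1 + inbreeding coefficient.
    """

    sample_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_order), len(self.sample_order)):
            raise ValueError("matrix shape does not match sample_order")

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.sample_order)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_order,
                            columns=self.sample_order)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(list(df.index), df.to_numpy(dtype=float))

    def write_cache(self, path: str | Path) -> None:
        """Compact binary cache (npz) for repeated pipeline runs."""
        np.savez_compressed(path, sample_order=np.array(self.sample_order),
                            values=self.values)

    @classmethod
    def read_cache(cls, path: str | Path) -> "RelationshipMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls([str(s) for s in z["sample_order"]], z["values"])


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def pedigree_file_hash(path: str | Path) -> str:
    """SHA-256 of the pedigree file, used to key the binary A-matrix cache."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_pedigree(path: str | Path,
                  on_missing_parent: Literal["error", "add_founder"] = "error",
                  ) -> Pedigree:
    """Read a PLINK-.fam-style pedigree file.

    Five whitespace/tab-delimited columns: family id, individual id, father,
    mother, sex; ``0`` (or empty) marks a missing parent.  With
    ``on_missing_parent="add_founder"``, parents referenced but absent from
    the file are added as founders of the same family with unknown sex.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise PedigreeError(
            f"expected 5 columns (FID IID father mother sex), got {df.shape[1]}"
        )
    df = df.iloc[:, :5].fillna(MISSING)
    records = []
    for fam, iid, fa, mo, sex in df.itertuples(index=False):
        records.append(PedigreeRecord(
            family_id=str(fam),
            individual_id=str(iid),
            father_id=None if str(fa) in ("", MISSING) else str(fa),
            mother_id=None if str(mo) in ("", MISSING) else str(mo),
            sex=_SEX_CODES.get(str(sex).strip().lower(), "unknown"),
        ))
    if on_missing_parent == "add_founder":
        known = {r.individual_id for r in records}
        extra: dict[str, str] = {}  # parent id -> family id
        for r in records:
            for p in (r.father_id, r.mother_id):
                if p is not None and p not in known:
                    extra.setdefault(p, r.family_id)
        for p, fam in extra.items():
            records.append(PedigreeRecord(fam, p, None, None, "unknown"))
    return Pedigree(records)


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix, in the pedigree's input order."""
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    n = ped.n
    A = np.zeros((n, n))
    for i, iid in enumerate(order):
        r = ped.record(iid)
        fi = pos[r.father_id] if r.father_id is not None else None
        mi = pos[r.mother_id] if r.mother_id is not None else None
        if i > 0:
            row = np.zeros(i)
            if fi is not None:
                row += 0.5 * A[:i, fi]
            if mi is not None:
                row += 0.5 * A[:i, mi]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[fi, mi] if fi is not None and mi is not None else 0.0)
    # restore input order
    perm = np.array([pos[iid] for iid in ped.individual_ids], dtype=int)
    return RelationshipMatrix(ped.individual_ids, A[np.ix_(perm, perm)])
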