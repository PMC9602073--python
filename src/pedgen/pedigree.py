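"""Pedigree container: loading, validation, topological ordering, reference subsets.

A :class:`Pedigree` stores animal records in topological order (every parent
precedes its offspring) and backs all downstream recursions with dense
integer parent indices.  Ids are opaque strings; ``-1`` marks an unknown
parent internally.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1

#: default tokens interpreted as "parent unknown"
DEFAULT_UNKNOWN_CODES = ("0", "", "NA", ".")

_SEX_MAP = {
    "m": "M", "male": "M", "1": "M",
    "f": "F", "female": "F", "2": "F",
}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, self-parents)."""


@dataclass(frozen=True)
class AnimalRecord:
    """One pedigree record. ``sire``/``dam`` are ``None`` when unknown."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "U"  # 'M', 'F' or 'U'
    birth_year: int | None = None

    def __post_init__(self):
        if not self.id:
            raise PedigreeError("animal id must be non-empty")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeError(f"animal {self.id!r} listed as its own parent")


@dataclass(frozen=True)
class ReferencePopulation:
    """A named subset of pedigree ids (e.g. the genotyped animals)."""

    ids: tuple[str, ...]
    description: str = ""

    @classmethod
    def from_file(cls, path, description: str = "") -> "ReferencePopulation":
        with open(path) as fh:
            ids = tuple(line.strip() for line in fh if line.strip())
        return cls(ids=ids, description=description)


class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Animal ids in topological order.
    sire, dam : ndarray of int
        Parent indices into ``ids`` (``UNKNOWN`` = -1).
    sex : ndarray of str
        'M', 'F' or 'U'.
    birth_year : ndarray of float
        Birth years, ``nan`` when missing.
    """

    def __init__(self, ids, sire, dam, sex, birth_year):
        self.ids: list[str] = list(ids)
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=object)
        self.birth_year = np.asarray(birth_year, dtype=float)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate ids after construction")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal_id) -> bool:
        return animal_id in self._index

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def is_founder(self) -> np.ndarray:
        """Boolean mask: both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def founders(self) -> list[str]:
        return [self.ids[i] for i in np.flatnonzero(self.is_founder)]

    def records(self):
        """Yield :class:`AnimalRecord` in topological order."""
        for i, a in enumerate(self.ids):
            yield AnimalRecord(
                id=a,
                sire=self.ids[self.sire[i]] if self.sire[i] != UNKNOWN else None,
                dam=self.ids[self.dam[i]] if self.dam[i] != UNKNOWN else None,
                sex=self.sex[i],
                birth_year=None if np.isnan(self.birth_year[i]) else int(self.birth_year[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.ids[s] if s != UNKNOWN else None for s in self.sire],
                "dam": [self.ids[d] if d != UNKNOWN else None for d in self.dam],
                "sex": self.sex,
                "birth_year": self.birth_year,
            }
        )

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build a pedigree from an iterable of :class:`AnimalRecord`.

        Parents referenced but never listed are materialized as founder
        records (unknown sex, missing birth year).  The result is sorted
        topologically; a cycle raises :class:`PedigreeError` naming one
        member of the cycle.
        """
        records = list(records)
        seen: dict[str, AnimalRecord] = {}
        for rec in records:
            if rec.id in seen:
                raise PedigreeError(f"duplicate id {rec.id!r}")
            seen[rec.id] = rec
        # auto-promote parents that appear only as parents
        for rec in records:
            for parent in (rec.sire, rec.dam):
                if parent is not None and parent not in seen:
                    seen[parent] = AnimalRecord(id=parent)
        order = _topological_order(seen)
        idx = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam = np.full(len(order), UNKNOWN, dtype=np.int64)
        sex = np.full(len(order), "U", dtype=object)
        year = np.full(len(order), np.nan)
        for a in order:
            rec = seen[a]
            i = idx[a]
            if rec.sire is not None:
                sire[i] = idx[rec.sire]
            if rec.dam is not None:
                dam[i] = idx[rec.dam]
            sex[i] = rec.sex
            if rec.birth_year is not None:
                year[i] = rec.birth_year
        return cls(order, sire, dam, sex, year)

    # -- subsets --------------------------------------------------------
    def ancestral_closure(self, ids) -> set[str]:
        """All ids in ``ids`` plus every traceable ancestor."""
        missing = [a for a in ids if a not in self._index]
        if missing:
            raise PedigreeError(f"unknown reference ids: {missing}")
        todo = deque(self._index[a] for a in ids)
        keep: set[int] = set()
        while todo:
            i = todo.popleft()
            if i in keep:
                continue
            keep.add(i)
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN and p not in keep:
                    todo.append(p)
        return {self.ids[i] for i in keep}

    def subset(self, keep_ids) -> "Pedigree":
        """Restrict to ``keep_ids``; parents outside the set become unknown."""
        keep = set(keep_ids)
        recs = []
        for i, a in enumerate(self.ids):
            if a not in keep:
                continue
            s = self.ids[self.sire[i]] if self.sire[i] != UNKNOWN else None
            d = self.ids[self.dam[i]] if self.dam[i] != UNKNOWN else None
            recs.append(
                AnimalRecord(
                    id=a,
                    sire=s if s in keep else None,
                    dam=d if d in keep else None,
                    sex=self.sex[i],
                    birth_year=None if np.isnan(self.birth_year[i]) else int(self.birth_year[i]),
                )
            )
        return Pedigree.from_records(recs)


def _topological_order(records: dict[str, AnimalRecord]) -> list[str]:
    """Kahn's algorithm over parent->offspring edges, stable in input order."""
    children: dict[str, list[str]] = {a: [] for a in records}
    indeg = {a: 0 for a in records}
    for rec in records.values():
        for parent in (rec.sire, rec.dam):
            if parent is not None:
                children[parent].append(rec.id)
                indeg[rec.id] += 1
    ready = deque(a for a in records if indeg[a] == 0)
    order: list[str] = []
    while ready:
        a = ready.popleft()
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(records):
        stuck = next(a for a in records if indeg[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {stuck!r}")
    return order


@dataclass
class PedigreeDialect:
    """Column mapping and codes for reading a pedigree table."""

    id_col: str = "id"
    sire_col: str = "sire"
    dam_col: str = "dam"
    sex_col: str | None = "sex"
    birth_year_col: str | None = "birth_year"
    unknown_codes: tuple[str, ...] = DEFAULT_UNKNOWN_CODES
    sep: str | None = None  # None = sniff (comma or whitespace)
    header: bool = True


def load_pedigree(path, dialect: PedigreeDialect | None = None) -> Pedigree:
    """Read a pedigree file (CSV or whitespace table) and return it sorted.

    Unknown parents are any token in ``dialect.unknown_codes`` (default
    includes ``"0"``).  Rows may appear in any order; the result is always
    topologically sorted.
    """
    dialect = dialect or PedigreeDialect()
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    sep = dialect.sep
    if sep is None:
        first = text.splitlines()[0] if text.splitlines() else ""
        sep = "," if "," in first else r"\s+"
    df = pd.read_csv(
        io.StringIO(text),
        sep=sep,
        header=0 if dialect.header else None,
        dtype=str,
        keep_default_na=False,
        engine="python",
    )
    if not dialect.header:
        names = [dialect.id_col, dialect.sire_col, dialect.dam_col]
        if dialect.sex_col:
            names.append(dialect.sex_col)
        if dialect.birth_year_col:
            names.append(dialect.birth_year_col)
        df.columns = names[: df.shape[1]]
    for col in (dialect.id_col, dialect.sire_col, dialect.dam_col):
        if col not in df.columns:
            raise PedigreeError(f"column {col!r} not found in {sorted(df.columns)}")
    unknown = set(dialect.unknown_codes)

    def parent(tok: str) -> str | None:
        tok = tok.strip()
        return None if tok in unknown else tok

    recs = []
    for _, row in df.iterrows():
        sex = "U"
        if dialect.sex_col and dialect.sex_col in df.columns:
            sex = _SEX_MAP.get(str(row[dialect.sex_col]).strip().lower(), "U")
        year = None
        if dialect.birth_year_col and dialect.birth_year_col in df.columns:
            tok = str(row[dialect.birth_year_col]).strip()
            if tok and tok not in unknown:
                try:
                    year = int(float(tok))
                except ValueError:
                    year = None
        recs.append(
            AnimalRecord(
                id=str(row[dialect.id_col]).strip(),
                sire=parent(str(row[dialect.sire_col])),
                dam=parent(str(row[dialect.dam_col])),
                sex=sex,
                birth_year=year,
            )
        )
    return Pedigree.from_records(recs)


def restrict_to_reference(ped: Pedigree, ref: ReferencePopulation) -> Pedigree:
    """Ancestral closure of ``ref``: the reference animals plus all ancestors.

    Per-animal pedigree statistics of the reference animals are identical in
    the restricted and the full pedigree, because every traceable ancestor is
    retained.
    """
    keep = ped.ancestral_closure(ref.ids)
    return ped.subset(keep)
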