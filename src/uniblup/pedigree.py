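"""Pedigree container.

A pedigree is an ordered list of (animal, sire, dam) records in which every
parent appears before any of its offspring.  Unknown parents are recorded with
an explicit sentinel (``None`` in memory, ``"0"`` or an empty field on disk).
The ordering requirement makes the tabular relationship-matrix recursion and
gene-dropping simulations single-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1

__all__ = ["Pedigree", "PedigreeError", "UNKNOWN"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unordered, cyclic, self-ancestry)."""


@dataclass
class Pedigree:
    """Ordered parent map.

    Attributes
    ----------
    ids : list of str
        Animal identifiers in topological order (parents before offspring).
    sire : numpy.ndarray of int
        Row index of each animal's sire, ``UNKNOWN`` (-1) if not recorded.
    dam : numpy.ndarray of int
        Row index of each animal's dam, ``UNKNOWN`` (-1) if not recorded.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(self.ids) != len(set(self.ids)):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise PedigreeError(f"duplicate animal id {dup!r}")
        self._index = {a: i for i, a in enumerate(self.ids)}
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            for p in (s, d):
                if p == i:
                    raise PedigreeError(f"animal {self.ids[i]!r} is its own parent")
                if p >= i:
                    # parents must precede offspring; a forward reference also
                    # covers any cycle, which cannot be topologically ordered
                    raise PedigreeError(
                        f"pedigree not ordered: parent of {self.ids[i]!r} "
                        f"appears at or after it"
                    )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build from (animal, sire, dam) tuples; ``None``/``"0"``/``""`` = unknown."""
        ids = [str(r[0]) for r in records]
        index = {a: i for i, a in enumerate(ids)}

        def code(p, child: str) -> int:
            if p is None or (isinstance(p, float) and np.isnan(p)):
                return UNKNOWN
            p = str(p)
            if p in ("", "0", "nan"):
                return UNKNOWN
            if p not in index:
                raise PedigreeError(f"parent {p!r} of {child!r} not in pedigree")
            return index[p]

        sire = np.array([code(r[1], str(r[0])) for r in records], dtype=np.int64)
        dam = np.array([code(r[2], str(r[0])) for r in records], dtype=np.int64)
        return cls(ids, sire, dam)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        """Read a CSV with header ``animal,sire,dam`` ("0" or empty = unknown)."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        for c in ("animal", "sire", "dam"):
            if c not in cols:
                raise PedigreeError(f"pedigree CSV missing column {c!r}")
        return cls.from_records(
            list(df[["animal", "sire", "dam"]].itertuples(index=False, name=None))
        )

    def to_csv(self, path) -> None:
        def name(p: int) -> str:
            return "0" if p == UNKNOWN else self.ids[p]

        pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [name(s) for s in self.sire],
                "dam": [name(d) for d in self.dam],
            }
        ).to_csv(path, index=False)

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal: str) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise KeyError(f"animal {animal!r} not in pedigree") from None

    def indices_of(self, animals) -> np.ndarray:
        return np.array([self.index_of(a) for a in animals], dtype=np.int64)

    @property
    def is_founder(self) -> np.ndarray:
        """True where both parents are unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def generation_index(self) -> np.ndarray:
        """0 for founders, else 1 + max(parent generation)."""
        gen = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            parents = [p for p in (self.sire[i], self.dam[i]) if p != UNKNOWN]
            if parents:
                gen[i] = 1 + max(gen[p] for p in parents)
        return gen

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        i = self.index_of(animal)
        s, d = self.sire[i], self.dam[i]
        return (
            self.ids[s] if s != UNKNOWN else None,
            self.ids[d] if d != UNKNOWN else None,
        )
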