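"""Disease-metabolite association tables.

The prior knowledge for the whole pipeline is a bipartite annotation set:
which metabolites are known to be associated with which diseases.  This
module reads, validates, summarizes and writes such tables, and fixes the
pair-counting convention used by every similarity summary downstream
(unordered pairs *including* self-pairs, i.e. ``n*(n+1)/2`` values among
``n`` entities).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "read_associations",
    "write_associations",
    "degree_stats",
    "pair_count",
]


class AssociationError(ValueError):
    """Raised when an association table violates its invariants."""


@dataclass(frozen=True)
class AssociationTable:
    """A validated bipartite disease-metabolite association set.

    Parameters
    ----------
    diseases : list of str
        Sorted, unique disease identifiers.
    metabolites : list of str
        Sorted, unique metabolite identifiers.
    pairs : frozenset of (str, str)
        The set of ``(disease_id, metabolite_id)`` associations.

    Identifier lists are sorted lexicographically so that matrix indexing
    is reproducible across runs.  Every identifier must take part in at
    least one pair: isolated entities would produce all-zero weight
    vectors and undefined cosines downstream, so they are rejected.
    """

    diseases: tuple[str, ...]
    metabolites: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]
    _disease_to_mets: dict[str, frozenset[str]] = field(
        repr=False, compare=False, default_factory=dict
    )
    _met_to_diseases: dict[str, frozenset[str]] = field(
        repr=False, compare=False, default_factory=dict
    )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        """Build and validate a table from an iterable of (disease, metabolite) pairs."""
        cleaned = {(str(d).strip(), str(m).strip()) for d, m in pairs}
        cleaned = {(d, m) for d, m in cleaned if d and m}
        if not cleaned:
            raise AssociationError("association table is empty")
        d2m: dict[str, set[str]] = {}
        m2d: dict[str, set[str]] = {}
        for d, m in cleaned:
            d2m.setdefault(d, set()).add(m)
            m2d.setdefault(m, set()).add(d)
        diseases = tuple(sorted(d2m))
        metabolites = tuple(sorted(m2d))
        table = cls(
            diseases=diseases,
            metabolites=metabolites,
            pairs=frozenset(cleaned),
            _disease_to_mets={d: frozenset(s) for d, s in d2m.items()},
            _met_to_diseases={m: frozenset(s) for m, s in m2d.items()},
        )
        return table

    # -- lookups ---------------------------------------------------------

    def metabolites_of(self, disease: str) -> frozenset[str]:
        """The metabolite set G of one disease."""
        try:
            return self._disease_to_mets[disease]
        except KeyError:
            raise KeyError(f"unknown disease id: {disease!r}") from None

    def diseases_of(self, metabolite: str) -> frozenset[str]:
        """The disease group D of one metabolite."""
        try:
            return self._met_to_diseases[metabolite]
        except KeyError:
            raise KeyError(f"unknown metabolite id: {metabolite!r}") from None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def remove_pair(self, disease: str, metabolite: str) -> "AssociationTable":
        """Return a new table with one association removed (for leave-one-out).

        Entities left isolated by the removal drop out of the id lists,
        matching the no-isolated-entity invariant.
        """
        if (disease, metabolite) not in self.pairs:
            raise KeyError(f"pair ({disease!r}, {metabolite!r}) not in table")
        remaining = set(self.pairs)
        remaining.discard((disease, metabolite))
        if not remaining:
            raise AssociationError("removal would empty the table")
        return AssociationTable.from_pairs(remaining)

    def to_frame(self) -> pd.DataFrame:
        """Pairs as a two-column DataFrame, sorted for stable output."""
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["disease_id", "metabolite_id"])


def read_associations(path: str | Path, format: str = "tsv") -> AssociationTable:
    """Read a disease-metabolite association table from a TSV file.

    The file must have a header row and exactly two tab-separated columns,
    ``disease_id`` and ``metabolite_id``, one pair per row.  Duplicate rows
    are dropped with a warning; malformed rows raise with a line number.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        lineno = 0
        header = ""
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                raise AssociationError(f"{path}: empty file")
            if header.strip() and not header.startswith("#"):
                break
        for lineno, line in enumerate(fh, start=lineno + 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise AssociationError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise AssociationError(f"{path}: no association rows")
    n_dup = len(pairs) - len(set(pairs))
    if n_dup:
        logger.warning("%s: %d duplicate row(s) dropped", path, n_dup)
    return AssociationTable.from_pairs(pairs)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    """Write a table back to the two-column TSV format."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def degree_stats(
    table: AssociationTable,
) -> tuple[dict[int, int], dict[int, int]]:
    """Frequency tables of annotation degrees.

    Returns
    -------
    (metabolites_per_disease, diseases_per_metabolite)
        Each maps ``k`` to the number of entities with exactly ``k``
        partners, so the values sum to the number of diseases (resp.
        metabolites) and ``sum(k * freq[k])`` equals the pair count.
    """
    mpd = Counter(len(table.metabolites_of(d)) for d in table.diseases)
    dpm = Counter(len(table.diseases_of(m)) for m in table.metabolites)
    return dict(sorted(mpd.items())), dict(sorted(dpm.items()))


def pair_count(n: int) -> int:
    """Number of similarity values among ``n`` entities: ``n*(n+1)/2``.

    Unordered pairs *including* self-pairs.  This is the convention under
    which 3,524 diseases yield 6,211,050 similarities and 604 metabolites
    yield 182,710.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return n * (n + 1) // 2
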