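"""Pedigree handling and numerator-relationship-matrix algebra.

A pedigree is a directed acyclic parentage structure over animal identifiers.
The additive (numerator) relationship matrix ``A`` implied by a pedigree has
``A[i, i] = 1 + F_i`` (``F_i`` the inbreeding coefficient) and off-diagonals
equal to twice the coefficient of coancestry.  Both the tabular construction
of ``A`` and Henderson's direct construction of ``A``:sup:`-1` (with full
accounting for parental inbreeding) are provided; they underpin every mixed
model in this package.

Unknown parents are base-population founders: in pedigree files they are an
empty field or ``"0"`` (``NA``/``na`` also accepted), internally index ``-1``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PedigreeError",
    "Pedigree",
    "validate_pedigree",
    "relationship_matrix",
    "inbreeding",
    "relationship_inverse",
    "read_pedigree",
    "write_pedigree",
]

#: sentinels accepted for an unknown parent in input records / files
UNKNOWN_SENTINELS = {"", "0", "na", "NA", "nan", None}


class PedigreeError(ValueError):
    """Structural or input error in a pedigree."""


def _is_unknown(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip() in UNKNOWN_SENTINELS


@dataclass(frozen=True)
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    animals :
        Animal identifiers in topological order (every parent precedes all of
        its offspring; ties broken by input order).
    sire, dam :
        Integer arrays of parent positions in ``animals``; ``-1`` = unknown
        (base-population founder).
    """

    animals: tuple
    sire: np.ndarray
    dam: np.ndarray
    index: dict = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.animals)

    def is_founder(self) -> np.ndarray:
        """Boolean mask of animals with both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    def positions(self, ids: Iterable) -> np.ndarray:
        """Map animal identifiers to their pedigree positions."""
        try:
            return np.array([self.index[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None

    def records(self):
        """Yield (animal, sire, dam) string triples, unknown parent = ''."""
        for i, a in enumerate(self.animals):
            s = self.animals[self.sire[i]] if self.sire[i] >= 0 else ""
            d = self.animals[self.dam[i]] if self.dam[i] >= 0 else ""
            yield a, s, d


def validate_pedigree(raw_records: Iterable[Sequence]) -> Pedigree:
    """Validate parent triples and return a topologically sorted pedigree.

    Parents that are referenced but never listed as animals themselves are
    appended as founders.  The sort is deterministic: among animals whose
    parents are already placed, input order decides.

    Raises
    ------
    PedigreeError
        On a duplicate animal identifier or a parentage cycle (the error
        message names one animal involved).
    """
    ids: list[str] = []
    parents: dict[str, tuple[str | None, str | None]] = {}
    for rec in raw_records:
        a, s, d = rec[0], rec[1], rec[2]
        if _is_unknown(a):
            raise PedigreeError("animal identifier may not be the unknown sentinel")
        a = str(a).strip()
        if a in parents:
            raise PedigreeError(f"duplicate animal id {a!r}")
        s = None if _is_unknown(s) else str(s).strip()
        d = None if _is_unknown(d) else str(d).strip()
        if s == a or d == a:
            raise PedigreeError(f"cycle detected involving animal {a!r} (own parent)")
        parents[a] = (s, d)
        ids.append(a)

    # referenced-but-unlisted parents become founders, in order of reference
    for a in list(ids):
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)
                ids.append(p)

    # Kahn's algorithm, stable in input order
    order_of_input = {a: i for i, a in enumerate(ids)}
    n_unplaced_parents = {
        a: sum(p is not None for p in parents[a]) for a in ids
    }
    children: dict[str, list[str]] = {a: [] for a in ids}
    for a in ids:
        for p in parents[a]:
            if p is not None:
                children[p].append(a)

    import heapq

    ready = [order_of_input[a] for a in ids if n_unplaced_parents[a] == 0]
    heapq.heapify(ready)
    sorted_ids: list[str] = []
    while ready:
        a = ids[heapq.heappop(ready)]
        sorted_ids.append(a)
        for c in children[a]:
            n_unplaced_parents[c] -= 1
            if n_unplaced_parents[c] == 0:
                heapq.heappush(ready, order_of_input[c])
    if len(sorted_ids) < len(ids):
        stuck = next(a for a in ids if n_unplaced_parents[a] > 0)
        raise PedigreeError(f"cycle detected involving animal {stuck!r}")

    index = {a: i for i, a in enumerate(sorted_ids)}
    sire = np.full(len(sorted_ids), -1, dtype=np.int64)
    dam = np.full(len(sorted_ids), -1, dtype=np.int64)
    for a, i in index.items():
        s, d = parents[a]
        if s is not None:
            sire[i] = index[s]
        if d is not None:
            dam[i] = index[d]
    return Pedigree(tuple(sorted_ids), sire, dam, index)


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix A by the tabular method.

    ``A[i, i] = 1 + 0.5 * A[s(i), d(i)]`` (term dropped when a parent is
    unknown) and ``A[i, j] = 0.5 * (A[j, s(i)] + A[j, d(i)])`` for ``j``
    earlier in pedigree order.
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (diag(A) - 1)."""
    return np.diag(relationship_matrix(ped)) - 1.0


def relationship_inverse(ped: Pedigree, sparse: bool = False):
    """Direct (Henderson-style) construction of A⁻¹, inbreeding included.

    Each animal contributes ``alpha = 1 / m_i`` where ``m_i`` is its
    Mendelian-sampling variance given its known parents:

    * both parents known:  ``0.5 - 0.25 (F_s + F_d)``
    * one parent known:    ``0.75 - 0.25 F_p``
    * founder:             ``1``

    Parameters
    ----------
    sparse :
        Return a ``scipy.sparse.csr_matrix`` instead of a dense array.
    """
    n = ped.n
    F = inbreeding(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = ped.sire[i], ped.dam[i]
        known = [p for p in (si, di) if p >= 0]
        m = 1.0 - 0.25 * sum(1.0 + F[p] for p in known)
        alpha = 1.0 / m
        add(i, i, alpha)
        for p in known:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
            for q in known:
                add(p, q, 0.25 * alpha)
    Ainv = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return Ainv if sparse else Ainv.toarray()


# ---------------------------------------------------------------------------
# file dialect: delimited text, header animal,sire,dam; unknown = "" or "0"
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file (comma or tab delimited, header required)."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["animal", "sire", "dam"]:
        raise PedigreeError(
            f"expected header animal,sire,dam in {path}, found {list(df.columns)!r}"
        )
    return validate_pedigree(df.itertuples(index=False, name=None))


def write_pedigree(ped: Pedigree, path, delimiter: str = ",") -> None:
    """Write a pedigree in the same dialect (explicit header)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["animal", "sire", "dam"])
        for rec in ped.records():
            w.writerow(rec)
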