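"""Pedigree handling and the additive genetic relationship matrix.

The breeding design is a classic half-sib scheme: field-derived colony
founders (sires and dams) are taken to be unrelated and non-inbred, each
sire is mated to several dams, and offspring form full-sib broods nested
within paternal half-sib families.  The numerator relationship matrix
``A`` built here is the covariance structure of additive genetic effects
used by the animal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNKNOWN = ""
#: strings accepted as "parent unknown" in pedigree files
_UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", ".", "*"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, orphans)."""


def _norm_parent(tok) -> str:
    if tok is None:
        return UNKNOWN
    if isinstance(tok, float) and np.isnan(tok):
        return UNKNOWN
    s = str(tok).strip()
    return UNKNOWN if s.lower() in _UNKNOWN_TOKENS else s


@dataclass(frozen=True)
class Pedigree:
    """A topologically sorted pedigree (parents always precede offspring).

    Attributes
    ----------
    ids : tuple of str
        Individual identifiers in generation order.
    sire_idx, dam_idx : ndarray of int
        Position of each individual's sire/dam in ``ids``; -1 for an
        unknown parent (founder).
    """

    ids: tuple
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    index: Mapping[str, int] = field(repr=False, default=None)

    def __post_init__(self):
        if self.index is None:
            object.__setattr__(self, "index", {i: k for k, i in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> tuple:
        return tuple(
            self.ids[k]
            for k in range(len(self))
            if self.sire_idx[k] < 0 and self.dam_idx[k] < 0
        )

    def parents_of(self, individual: str) -> tuple:
        k = self.index[individual]
        s = self.ids[self.sire_idx[k]] if self.sire_idx[k] >= 0 else UNKNOWN
        d = self.ids[self.dam_idx[k]] if self.dam_idx[k] >= 0 else UNKNOWN
        return s, d

    def to_frame(self) -> pd.DataFrame:
        sires = [self.ids[k] if k >= 0 else "" for k in self.sire_idx]
        dams = [self.ids[k] if k >= 0 else "" for k in self.dam_idx]
        return pd.DataFrame({"id": list(self.ids), "sire": sires, "dam": dams})


@dataclass(frozen=True)
class KinshipMatrix:
    """Additive (numerator) relationship matrix with its row/column ids."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match ids")

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        """Dense A restricted to (and ordered by) ``ids``."""
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"individual {e.args[0]!r} not in kinship matrix") from None
        return self.values[np.ix_(idx, idx)]


def build_pedigree(records, allow_implicit_founders: bool = False) -> Pedigree:
    """Validate and topologically sort raw pedigree records.

    Parameters
    ----------
    records : DataFrame with columns id/sire/dam, or iterable of
        (id, sire, dam) triples.  Unknown parents may be encoded as empty
        strings, ``0``, ``NA`` or None.
    allow_implicit_founders : bool
        If True, a parent referenced but never listed as an individual is
        inserted as a founder; if False this is an error.

    Raises
    ------
    PedigreeError
        On duplicate ids, undefined parents (unless implicit founders are
        allowed), or cycles (an individual among its own ancestors).
    """
    if isinstance(records, pd.DataFrame):
        triples = [
            (str(r.id).strip(), _norm_parent(r.sire), _norm_parent(r.dam))
            for r in records.itertuples(index=False)
        ]
    else:
        triples = [(str(i).strip(), _norm_parent(s), _norm_parent(d)) for i, s, d in records]

    ids = [t[0] for t in triples]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise PedigreeError(f"duplicate individual id(s): {sorted(set(dups))}")

    listed = set(ids)
    referenced = {p for _, s, d in triples for p in (s, d) if p != UNKNOWN}
    missing = sorted(referenced - listed)
    if missing:
        if not allow_implicit_founders:
            raise PedigreeError(
                f"parent(s) referenced but never listed: {missing} "
                "(set allow_implicit_founders=True to insert them as founders)"
            )
        triples = [(m, UNKNOWN, UNKNOWN) for m in missing] + triples
        ids = [t[0] for t in triples]

    parent_map = {i: (s, d) for i, s, d in triples}

    # Kahn-style topological sort on the parent -> offspring DAG.
    order: list[str] = []
    state: dict[str, int] = {}  # 0 unseen, 1 in progress, 2 done

    def visit(node: str, stack: list[str]):
        st = state.get(node, 0)
        if st == 2:
            return
        if st == 1:
            cyc = stack[stack.index(node):] + [node]
            raise PedigreeError(f"pedigree cycle detected: {' -> '.join(cyc)}")
        state[node] = 1
        stack.append(node)
        for p in parent_map[node]:
            if p != UNKNOWN:
                visit(p, stack)
        stack.pop()
        state[node] = 2
        order.append(node)

    for i in ids:
        visit(i, [])

    pos = {i: k for k, i in enumerate(order)}
    sire_idx = np.array(
        [pos[parent_map[i][0]] if parent_map[i][0] != UNKNOWN else -1 for i in order],
        dtype=int,
    )
    dam_idx = np.array(
        [pos[parent_map[i][1]] if parent_map[i][1] != UNKNOWN else -1 for i in order],
        dtype=int,
    )
    return Pedigree(ids=tuple(order), sire_idx=sire_idx, dam_idx=dam_idx)


def additive_relationship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Numerator relationship matrix A by the recursive tabular method.

    ``A[i,i] = 1 + A[sire(i), dam(i)] / 2`` and
    ``A[i,j] = (A[j, sire(i)] + A[j, dam(i)]) / 2`` for j preceding i;
    unknown parents contribute zero relationship and no inbreeding, i.e.
    founders are unrelated and non-inbred.  The matrix is returned dense:
    the breeding designs this package targets stay near ~10^3 individuals.
    """
    n = len(ped)
    A = np.zeros((n, n), dtype=float)
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if i > 0:
            j = np.arange(i)
            row = np.zeros(i)
            if si >= 0:
                row += A[j, si]
            if di >= 0:
                row += A[j, di]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return KinshipMatrix(ids=ped.ids, values=A)
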