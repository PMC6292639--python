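"""Pedigrees and the additive (numerator) relationship matrix.

The additive genetic covariance between individuals in an animal model is
``A * sigma_u^2`` where ``A`` is the numerator relationship matrix implied by
the pedigree: ``a_ii = 1 + F_i`` (``F_i`` the inbreeding coefficient) and
``a_ij`` the expected additive relationship.  The mixed-model equations need
``A^{-1}``, which is sparse and can be assembled directly from the pedigree
with Henderson's rules, corrected for inbreeding via Meuwissen & Luo-style
computation of ``F`` during a single pass.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "tabular_relationship",
    "inbreeding_coefficients",
    "build_a_inverse",
]

UNKNOWN = 0  # sentinel for an unknown parent in input files


class PedigreeError(ValueError):
    """Invalid pedigree structure (duplicate IDs, cycles, ...)."""


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    Internally animals are numbered ``1..q`` such that every parent precedes
    its offspring; ``sire[i]`` / ``dam[i]`` hold the internal parent codes of
    animal ``i + 1`` (0 = unknown).  ``original_ids`` maps internal code
    ``i + 1`` back to the identifier used in the input.
    """

    sire: np.ndarray
    dam: np.ndarray
    original_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape:
            raise PedigreeError("sire and dam arrays differ in length")
        if self.original_ids is None:
            self.original_ids = np.arange(1, self.n_animals + 1)
        self.original_ids = np.asarray(self.original_ids)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = (par < 0) | (par > np.arange(len(par)))
            if bad.any():
                raise PedigreeError(
                    f"{name} code must reference an earlier animal or 0 "
                    f"(first offender at position {int(np.where(bad)[0][0])})"
                )

    @property
    def n_animals(self) -> int:
        return len(self.sire)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def id_to_code(self) -> dict:
        """Map original identifier -> internal 1-based code."""
        return {oid: i + 1 for i, oid in enumerate(self.original_ids)}

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as a DataFrame of original IDs (0 = unknown parent)."""
        orig = np.concatenate(([0], self.original_ids))
        return pd.DataFrame(
            {
                "animal": self.original_ids,
                "sire": orig[self.sire],
                "dam": orig[self.dam],
            }
        )

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _toposort(animals, sires, dams):
    """Order entries so parents precede offspring; detect cycles."""
    index = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    order: list[int] = []
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in stack, 2 done
    for start in range(n):
        if state[start]:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                raise PedigreeError(
                    f"animal {animals[node]!r} is its own ancestor"
                )
            state[node] = 1
            stack.append((node, True))
            for parent in (sires[node], dams[node]):
                if parent == UNKNOWN:
                    continue
                p = index[parent]
                if state[p] == 1:
                    raise PedigreeError(
                        f"animal {animals[p]!r} is its own ancestor"
                    )
                if state[p] == 0:
                    stack.append((p, False))
    return order


def _sniff_table(path) -> pd.DataFrame:
    """Read a whitespace- or comma-delimited table, header auto-detected."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    sep = "," if ("," in text.splitlines()[0] if text.strip() else False) else r"\s+"
    first = pd.read_csv(io.StringIO(text), sep=sep, header=None, nrows=1)
    has_header = any(
        isinstance(v, str) and not v.lstrip("-").isdigit() for v in first.iloc[0]
    )
    return pd.read_csv(io.StringIO(text), sep=sep, header=0 if has_header else None)


def read_pedigree(path) -> Pedigree:
    """Read and validate an animal/sire/dam pedigree file.

    The file is whitespace- or comma-delimited with at least three columns
    (animal, sire, dam); ``0`` codes an unknown parent; a header row is
    auto-detected.  Parents that never appear in the animal column are
    auto-promoted to founders (with a warning).  Returns a topologically
    ordered :class:`Pedigree` with original IDs retained.
    """
    df = _sniff_table(path)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs >= 3 columns (animal, sire, dam)")
    animals = list(df.iloc[:, 0])
    sires = list(df.iloc[:, 1])
    dams = list(df.iloc[:, 2])

    seen = set()
    for a in animals:
        if a in seen:
            raise PedigreeError(f"duplicate animal ID {a!r}")
        if a == UNKNOWN:
            raise PedigreeError("animal ID 0 clashes with the unknown-parent code")
        seen.add(a)
    missing = [
        p for p in dict.fromkeys(sires + dams) if p != UNKNOWN and p not in seen
    ]
    if missing:
        warnings.warn(
            f"{len(missing)} parent ID(s) never listed as animals; "
            "auto-promoted to founders",
            stacklevel=2,
        )
        animals = missing + animals
        sires = [UNKNOWN] * len(missing) + sires
        dams = [UNKNOWN] * len(missing) + dams

    order = _toposort(animals, sires, dams)
    code = {animals[node]: rank + 1 for rank, node in enumerate(order)}
    q = len(animals)
    sire = np.zeros(q, dtype=np.int64)
    dam = np.zeros(q, dtype=np.int64)
    orig = np.empty(q, dtype=object)
    for rank, node in enumerate(order):
        orig[rank] = animals[node]
        if sires[node] != UNKNOWN:
            sire[rank] = code[sires[node]]
        if dams[node] != UNKNOWN:
            dam[rank] = code[dams[node]]
    try:
        orig = orig.astype(np.int64)
    except (TypeError, ValueError):
        pass
    return Pedigree(sire=sire, dam=dam, original_ids=orig)


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    ``a_ij = 0.5 (a_{i,s_j} + a_{i,d_j})`` for ``i < j`` and
    ``a_jj = 1 + 0.5 a_{s_j, d_j}``; unknown parents contribute 0.
    Intended as the small-scale oracle for :func:`build_a_inverse`.
    """
    q = ped.n_animals
    A = np.zeros((q, q))
    s = ped.sire - 1
    d = ped.dam - 1
    for j in range(q):
        sj, dj = s[j], d[j]
        A[j, j] = 1.0 + (0.5 * A[sj, dj] if sj >= 0 and dj >= 0 else 0.0)
        for i in range(j):
            a = 0.0
            if sj >= 0:
                a += 0.5 * A[i, sj]
            if dj >= 0:
                a += 0.5 * A[i, dj]
            A[i, j] = A[j, i] = a
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo recursion.

    For each animal the vector of ancestral contributions ``L`` is traced
    back through the ordered pedigree; ``1 + F_i = sum_j L_j^2 d_j`` with
    ``d_j`` the Mendelian-sampling variance ratio of ancestor ``j``.
    """
    q = ped.n_animals
    s = ped.sire - 1
    d = ped.dam - 1
    F = np.zeros(q)
    D = np.zeros(q)  # filled lazily in ancestor order
    for i in range(q):
        si, di = s[i], d[i]
        if si < 0 and di < 0:
            F[i] = 0.0
            D[i] = 1.0
            continue
        aii = 0.0
        # walk ancestors from youngest to oldest
        pending = [i]
        Lvals = {i: 1.0}
        while pending:
            j = max(pending)
            pending.remove(j)
            lj = Lvals.pop(j)
            dj = _mendelian_d(F, s[j], d[j])
            aii += lj * lj * dj
            for p in (s[j], d[j]):
                if p >= 0:
                    if p in Lvals:
                        Lvals[p] += 0.5 * lj
                    else:
                        Lvals[p] = 0.5 * lj
                        pending.append(p)
        F[i] = aii - 1.0
        D[i] = _mendelian_d(F, si, di)
    return F


def _mendelian_d(F: np.ndarray, s: int, d: int) -> float:
    """Mendelian sampling variance ratio d_i given parent codes (-1 unknown)."""
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0:
        return 0.75 - 0.25 * F[s]
    if d >= 0:
        return 0.75 - 0.25 * F[d]
    return 1.0


def build_a_inverse(ped: Pedigree, ignore_inbreeding: bool = False) -> sparse.csr_matrix:
    """Sparse inverse of the numerator relationship matrix.

    Henderson's rules: for animal ``i`` with Mendelian sampling variance
    ratio ``d_i``, add ``1/d_i`` at ``(i,i)``, ``-0.5/d_i`` at ``(i,parent)``
    and ``0.25/d_i`` between parents.  By default ``d_i`` uses the true
    inbreeding coefficients so that ``A^{-1} A = I`` exactly; with
    ``ignore_inbreeding=True`` the simple rules (F = 0) are used instead.
    """
    q = ped.n_animals
    s = ped.sire - 1
    d = ped.dam - 1
    F = np.zeros(q) if ignore_inbreeding else inbreeding_coefficients(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(q):
        parents = [p for p in (s[i], d[i]) if p >= 0]
        inv_d = 1.0 / _mendelian_d(F, s[i], d[i])
        add(i, i, inv_d)
        for p in parents:
            add(i, p, -0.5 * inv_d)
            add(p, i, -0.5 * inv_d)
        for p in parents:
            for pp in parents:
                add(p, pp, 0.25 * inv_d)
    a_inv = sparse.coo_matrix((vals, (rows, cols)), shape=(q, q)).tocsr()
    a_inv.sum_duplicates()
    return a_inv
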