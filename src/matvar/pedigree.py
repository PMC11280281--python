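"""Pedigree handling and the numerator relationship matrix.

The additive-genetic covariance structure of an animal model is carried by
the numerator relationship matrix A, whose entry ``a_ij`` is twice the
kinship between animals i and j and whose diagonal is ``1 + F_i`` with
``F_i`` the inbreeding coefficient.  This module parses raw pedigree files,
renumbers animals so that parents always precede offspring, computes
inbreeding with the Meuwissen & Luo recursion, builds dense A by the tabular
method, and assembles the sparse inverse directly with Henderson's rules
(accounting for parental inbreeding).

Unknown parents (coded 0 or empty) are treated as draws from an unrelated,
non-inbred base population; there is no phantom-parent grouping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "load_and_renumber",
    "renumber",
    "compute_inbreeding",
    "a_matrix",
    "a_inverse",
]

DENSE_A_CAP = 5_000  # refuse dense A above this many animals unless overridden


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, self-parenting, ...)."""


@dataclass
class PedigreeTable:
    """Renumbered pedigree: ids 1..q, parents precede offspring, 0 = unknown.

    Attributes
    ----------
    sire, dam
        Integer arrays of length q; entry i-1 is the parent id of animal i
        (0 when unknown).  Topological order guarantees sire[i-1] < i and
        dam[i-1] < i.
    inbreeding
        Per-animal inbreeding coefficients F in [0, 1]; founders have F = 0.
        Computed lazily by :func:`compute_inbreeding`.
    labels
        Original labels in renumbered order (labels[i-1] is the raw id of
        animal i), so results can be reported in the caller's identifiers.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: list = field(default_factory=list)
    inbreeding: np.ndarray | None = None

    @property
    def q(self) -> int:
        return len(self.sire)

    def label_map(self) -> dict:
        return {lab: i + 1 for i, lab in enumerate(self.labels)}

    def f(self) -> np.ndarray:
        if self.inbreeding is None:
            self.inbreeding = compute_inbreeding(self)
        return self.inbreeding

    def write_renumber_map(self, path: str | Path) -> None:
        """Persist the label -> new-id map as two-column text."""
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels, start=1):
                fh.write(f"{lab}\t{i}\n")


def _read_pedigree_frame(source) -> pd.DataFrame:
    """Read a 3+ column whitespace- or comma-delimited pedigree file.

    A header row is detected by a non-numeric first field and skipped.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    sep = "," if ("," in text.splitlines()[0] if text.strip() else False) else None
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                     comment="#", skip_blank_lines=True,
                     engine="python" if sep is None else "c")
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file must have at least 3 columns (animal, sire, dam)")
    first = str(df.iloc[0, 0]).strip()
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise PedigreeError("pedigree file contains no rows")
    df = df.iloc[:, :3]
    df.columns = ["animal", "sire", "dam"]
    for c in df.columns:
        df[c] = df[c].astype(str).str.strip()
    return df


_UNKNOWN = {"0", "", "nan", "NA", ".", "None"}


def renumber(triples: list[tuple]) -> PedigreeTable:
    """Renumber (animal, sire, dam) label triples topologically.

    Animals that appear only as parents are inserted as founders.  Duplicate
    animal rows with conflicting parents raise; consistent duplicates are
    merged.  Cycles and self-parenting raise :class:`PedigreeError`.
    """
    parents: dict = {}
    order: list = []
    for a, s, d in triples:
        s = None if str(s) in _UNKNOWN else s
        d = None if str(d) in _UNKNOWN else d
        if a is None or str(a) in _UNKNOWN:
            raise PedigreeError("animal id missing in pedigree row")
        if a == s or a == d:
            raise PedigreeError(f"animal {a!r} is its own parent")
        if a in parents:
            if parents[a] != (s, d):
                raise PedigreeError(f"conflicting parent records for animal {a!r}")
            continue
        parents[a] = (s, d)
        order.append(a)
    # parents never declared as animals become founders
    for a in list(order):
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)
                order.append(p)

    # iterative DFS topological sort, detecting cycles
    seq: list = []
    state: dict = {}  # 0 visiting, 1 done
    for root in order:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                seq.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle detected involving animal {node!r}")
            state[node] = 0
            stack.append((node, True))
            for p in parents[node]:
                if p is not None and state.get(p) != 1:
                    if state.get(p) == 0:
                        raise PedigreeError(
                            f"pedigree cycle detected involving animal {p!r}")
                    stack.append((p, False))

    idx = {lab: i + 1 for i, lab in enumerate(seq)}
    q = len(seq)
    sire = np.zeros(q, dtype=np.int64)
    dam = np.zeros(q, dtype=np.int64)
    for lab in seq:
        i = idx[lab]
        s, d = parents[lab]
        sire[i - 1] = idx[s] if s is not None else 0
        dam[i - 1] = idx[d] if d is not None else 0
    return PedigreeTable(sire=sire, dam=dam, labels=seq)


def load_and_renumber(pedigree_file, records_file=None,
                      map_file: str | Path | None = None) -> PedigreeTable:
    """Load a pedigree file, validate it and renumber animals 1..q.

    Animals appearing only in ``records_file`` (CSV with an ``animal``
    column) are appended as founders so every record can be linked.  If
    ``map_file`` is given the label -> id map is written there.
    """
    df = _read_pedigree_frame(pedigree_file)
    triples = list(df.itertuples(index=False, name=None))
    if records_file is not None:
        rec = pd.read_csv(records_file, dtype={"animal": str})
        known = {str(t[0]) for t in triples}
        for a in rec["animal"].astype(str):
            if a not in known and a not in _UNKNOWN:
                triples.append((a, "0", "0"))
                known.add(a)
    ped = renumber(triples)
    ped.f()
    if map_file is not None:
        ped.write_renumber_map(map_file)
    return ped


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

    ``F_i = 0.5 * a(sire_i, dam_i)``, evaluated without forming A: for each
    animal the L-row of the Cholesky factor of A is traced back through the
    pedigree and F accumulates as ``sum(L_ij^2 * d_j) - 1``.
    """
    q = ped.q
    s = ped.sire
    d = ped.dam
    f = np.zeros(q + 1)  # 1-based; f[0] unused
    dvec = np.zeros(q + 1)  # Mendelian sampling variance of each animal
    for i in range(1, q + 1):
        si, di = s[i - 1], d[i - 1]
        fs = f[si] if si else -1.0  # convention: F of unknown parent = -1
        fd = f[di] if di else -1.0
        dvec[i] = 0.5 - 0.25 * (fs + fd)
        if si == 0 or di == 0:
            f[i] = 0.0
            continue
        # trace ancestors of i youngest-first, accumulating L-row coefficients;
        # a_ii = sum_j L_ij^2 d_j (own term L_ii = 1 contributes dvec[i])
        fi = dvec[i] - 1.0
        pending: dict[int, float] = {si: 0.5, di: 0.5}
        while pending:
            j = max(pending)
            lj = pending.pop(j)
            fi += lj * lj * dvec[j]
            sj, dj = s[j - 1], d[j - 1]
            if sj:
                pending[sj] = pending.get(sj, 0.0) + 0.5 * lj
            if dj:
                pending[dj] = pending.get(dj, 0.0) + 0.5 * lj
        f[i] = fi
    out = f[1:].copy()
    ped.inbreeding = out
    return out


def a_matrix(ped: PedigreeTable, cap: int = DENSE_A_CAP) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    ``a_ii = 1 + F_i``; ``a_ij = 0.5 * (a_j,sire(i) + a_j,dam(i))`` for j < i.
    Refuses pedigrees larger than ``cap`` animals (dense memory guard).
    """
    q = ped.q
    if q > cap:
        raise PedigreeError(
            f"dense A refused for q={q} > cap={cap}; raise `cap` explicitly if intended")
    A = np.zeros((q, q))
    s, d = ped.sire, ped.dam
    for i in range(q):
        si, di = s[i] - 1, d[i] - 1  # -1 means unknown
        for j in range(i):
            aij = 0.0
            if si >= 0:
                aij += 0.5 * A[j, si]
            if di >= 0:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
        aii = 1.0
        if si >= 0 and di >= 0:
            aii += 0.5 * A[si, di]
        A[i, i] = aii
    ped.inbreeding = np.diag(A) - 1.0
    return A


def a_inverse(ped: PedigreeTable, use_inbreeding: bool = True) -> sparse.csr_matrix:
    """Sparse A^-1 assembled directly by Henderson's rules.

    Each animal contributes ``alpha_i = 1/delta_i`` where ``delta_i`` is its
    Mendelian sampling variance: 0.5 - 0.25 (F_s + F_d) with both parents
    known, 0.75 - 0.25 F_p with one, 1 with none.  Setting
    ``use_inbreeding=False`` applies the classic no-inbreeding simplification
    (delta from parent counts only).
    """
    q = ped.q
    f = ped.f() if use_inbreeding else np.zeros(q)
    s, d = ped.sire, ped.dam
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(1, q + 1):
        si, di = s[i - 1], d[i - 1]
        fs = f[si - 1] if si else 0.0
        fd = f[di - 1] if di else 0.0
        if si and di:
            delta = 0.5 - 0.25 * (fs + fd)
        elif si or di:
            delta = 0.75 - 0.25 * (fs if si else fd)
        else:
            delta = 1.0
        if delta <= 0:
            raise PedigreeError(
                f"non-positive Mendelian sampling variance for animal {i}: "
                "inbreeding input is corrupt")
        alpha = 1.0 / delta
        add(i - 1, i - 1, alpha)
        for p in (si, di):
            if p:
                add(i - 1, p - 1, -0.5 * alpha)
                add(p - 1, i - 1, -0.5 * alpha)
                add(p - 1, p - 1, 0.25 * alpha)
        if si and di:
            add(si - 1, di - 1, 0.25 * alpha)
            add(di - 1, si - 1, 0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(q, q)).tocsr()
    Ainv.sum_duplicates()
    return Ainv
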