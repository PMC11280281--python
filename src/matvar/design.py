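"""Fixed/random-effect incidence structure for the three candidate models.

The models partition phenotypic variance progressively:

* M1: y = Xb + Zu + e                      (direct additive only)
* M2: y = Xb + Zu + Wd + e                 (+ maternal genetic, with
                                            direct-maternal covariance)
* M3: y = Xb + Zu + Wd + M_pe pe + e       (+ maternal permanent environment)

X carries an intercept plus reference-coded generation and hatch dummies
(first level of each factor dropped — any full-rank coding yields identical
variance components).  Z links records to the animal's own breeding value,
W to the dam's maternal breeding value (columns index pedigree animals,
because dams are animals), and M_pe to a dam-identity factor with one column
per dam that has progeny records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy import sparse

from .qc import TraitRecords

__all__ = ["ModelSpec", "DesignMatrices", "build_design", "MODELS"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Which random effects a candidate model fits."""

    model_id: str  # "M1" | "M2" | "M3"
    has_maternal_genetic: bool
    has_maternal_pe: bool
    fixed_factors: tuple = ("generation", "hatch")

    def __post_init__(self):
        flags = {"M1": (False, False), "M2": (True, False), "M3": (True, True)}
        if self.model_id not in flags:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if (self.has_maternal_genetic, self.has_maternal_pe) != flags[self.model_id]:
            raise ValueError(f"inconsistent flags for {self.model_id}")

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        flags = {"M1": (False, False), "M2": (True, False), "M3": (True, True)}
        g, pe = flags[model_id]
        return cls(model_id, g, pe)

    @property
    def complexity(self) -> int:
        return 1 + self.has_maternal_genetic + self.has_maternal_pe


MODELS = {mid: ModelSpec.from_id(mid) for mid in ("M1", "M2", "M3")}


@dataclass
class DesignMatrices:
    """Sparse incidence matrices for one trait under one model.

    ``W`` and ``Mpe`` are None for models that do not fit the corresponding
    effect.  ``dams`` lists, in Mpe column order, the pedigree ids of dams
    with progeny records.  ``y`` is the record vector in row order.
    """

    X: sparse.csr_matrix
    Z: sparse.csr_matrix
    W: sparse.csr_matrix | None
    Mpe: sparse.csr_matrix | None
    y: np.ndarray
    spec: ModelSpec
    fixed_names: list[str]
    dams: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def n_dams(self) -> int:
        return 0 if self.Mpe is None else self.Mpe.shape[1]

    def stacked(self) -> sparse.csr_matrix:
        """T = [X Z (W) (Mpe)] — the full location-effect incidence."""
        blocks = [self.X, self.Z]
        if self.W is not None:
            blocks.append(self.W)
        if self.Mpe is not None:
            blocks.append(self.Mpe)
        return sparse.hstack(blocks, format="csr")


def _dummy_code(levels: np.ndarray, factor: str) -> tuple[sparse.csr_matrix, list[str]]:
    """Reference-coded dummies: first (sorted) level dropped."""
    cats = np.unique(levels)
    cols = cats[1:]
    n = len(levels)
    idx = {c: j for j, c in enumerate(cols)}
    rows, jcol = [], []
    for i, lev in enumerate(levels):
        if lev in idx:
            rows.append(i)
            jcol.append(idx[lev])
    M = sparse.csr_matrix((np.ones(len(rows)), (rows, jcol)), shape=(n, len(cols)))
    return M, [f"{factor}[{c}]" for c in cols]


def _one_hot(col_ids: np.ndarray, n_cols: int) -> sparse.csr_matrix:
    n = len(col_ids)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), col_ids)), shape=(n, n_cols))


def build_design(records: TraitRecords, ped, spec: ModelSpec) -> DesignMatrices:
    """Assemble X, Z, W, Mpe and y for one trait under one model.

    Under M2/M3 a record whose dam is unknown has no defined maternal link;
    such records are excluded with a logged count.  Raises if that would
    exclude everything.
    """
    records.validate_against_pedigree(ped)
    df = records.data
    n_excluded = 0
    if spec.has_maternal_genetic:
        known = df["dam"].to_numpy() != 0
        n_excluded = int((~known).sum())
        if n_excluded:
            log.info("%s/%s: excluded %d records with unknown dam under %s",
                     records.trait_name, spec.model_id, n_excluded, spec.model_id)
        df = df[known].reset_index(drop=True)
        if df.empty:
            raise ValueError(
                f"all {records.trait_name!r} records have unknown dams; "
                f"{spec.model_id} cannot be fitted")

    n = len(df)
    x_blocks = [sparse.csr_matrix(np.ones((n, 1)))]
    names = ["intercept"]
    for factor in spec.fixed_factors:
        M, nm = _dummy_code(df[factor].to_numpy(), factor)
        if M.shape[1]:
            x_blocks.append(M)
            names.extend(nm)
    X = sparse.hstack(x_blocks, format="csr")

    animal = df["animal"].to_numpy(dtype=int)
    Z = _one_hot(animal - 1, ped.q)
    W = Mpe = None
    dams = np.array([], dtype=int)
    if spec.has_maternal_genetic:
        dam = df["dam"].to_numpy(dtype=int)
        W = _one_hot(dam - 1, ped.q)
        if spec.has_maternal_pe:
            dams = np.unique(dam)
            dam_col = {d: j for j, d in enumerate(dams)}
            Mpe = _one_hot(np.array([dam_col[d] for d in dam]), len(dams))
    return DesignMatrices(X=X, Z=Z, W=W, Mpe=Mpe,
                          y=df["value"].to_numpy(dtype=float), spec=spec,
                          fixed_names=names, dams=dams, n_excluded=n_excluded)
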