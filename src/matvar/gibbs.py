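"""Gibbs sampler for pedigree animal models with maternal effects.

Each iteration alternates between

1. single-site (scalar) Gibbs updates of all location effects -- fixed
   effects, breeding values, maternal breeding values, permanent
   environmental effects -- drawn from their normal full conditionals under
   the mixed-model-equations coefficient structure (A^-1 x G^-1
   contributions for the genetic effects, I/sigma2_pe for the permanent
   environment);
2. variance-component updates: a scaled-inverse-chi-square draw for a lone
   additive variance, an inverse-Wishart draw for the 2x2 direct/maternal
   genetic covariance matrix (scale u'A^-1u, u'A^-1d, d'A^-1d plus prior),
   and scaled-inverse-chi-square draws for sigma2_pe (from pe'pe) and
   sigma2_e (from e'e).

Randomness is consumed in a fixed, documented order from one seeded
generator per chain, so runs are bitwise reproducible.  The conditional
deviance -2 log N(y | location fit, I sigma2_e) is recorded at every
retained draw for DIC.

A bivariate chain (direct-additive structure per trait, shared pedigree)
samples 2x2 genetic and residual covariance matrices; records missing for
one trait are handled by data augmentation (the missing residual is imputed
from its conditional normal given the observed trait's residual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .design import DesignMatrices, ModelSpec, build_design
from .pedigree import PedigreeTable, a_inverse
from .qc import TraitRecords

__all__ = [
    "ChainConfig",
    "Priors",
    "VarianceState",
    "PosteriorChain",
    "BivariateChain",
    "run_chain",
    "run_bivariate_chain",
    "sample_scaled_inv_chi2",
]

_PARAM_ORDER = ["sigma2_a", "sigma2_m", "sigma_am", "sigma2_pe", "sigma2_e"]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class Priors:
    """Variance-component priors.

    ``mode="weak"`` (default): scaled-inverse-chi-square with ``df_scalar``
    degrees of freedom for each scalar variance and an inverse-Wishart with
    ``df_matrix`` for the 2x2 genetic covariance; the prior scale of every
    component is half the sample phenotypic variance split evenly across the
    fitted components (off-diagonal prior scale 0).  ``mode="flat"`` sets
    all prior df and scales to zero, leaving the data sums of squares alone.
    """

    mode: str = "weak"
    df_scalar: float = 2.0
    df_matrix: float = 3.0

    def resolve(self, var_y: float, n_components: int):
        if self.mode == "flat":
            return 0.0, 0.0, 0.0, np.zeros((2, 2))
        share = 0.5 * var_y / n_components
        return self.df_scalar, share * self.df_scalar, self.df_matrix, \
            np.diag([share, share])


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain protocol: total rounds, burn-in, thinning, seed, priors."""

    n_iterations: int = 200_000
    burn_in: int = 2_000
    thin: int = 50
    seed: int = 0
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class VarianceState:
    """One draw of the variance components, in squared trait units."""

    sigma2_a: float
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_pe: float = 0.0
    sigma2_e: float = 1.0

    def as_tuple(self):
        return (self.sigma2_a, self.sigma2_m, self.sigma_am,
                self.sigma2_pe, self.sigma2_e)


@dataclass
class PosteriorChain:
    """Retained thinned draws from one univariate run.

    ``draws`` has one row per retained draw with the variance components and
    the conditional deviance; ``mean_fitted`` and ``mean_sigma2_e`` are the
    posterior-mean plug-ins needed for DIC.
    """

    draws: pd.DataFrame
    model: ModelSpec
    config: ChainConfig
    n_records: int
    y: np.ndarray
    mean_fitted: np.ndarray
    trait_name: str = ""
    n_excluded: int = 0
    record_key: tuple = ()

    @property
    def mean_sigma2_e(self) -> float:
        return float(self.draws["sigma2_e"].mean())

    def states(self):
        for row in self.draws.itertuples(index=False):
            yield VarianceState(row.sigma2_a, row.sigma2_m, row.sigma_am,
                                row.sigma2_pe, row.sigma2_e)


@dataclass
class BivariateChain:
    """Retained draws of 2x2 genetic (G0) and residual (R0) covariances."""

    g_draws: np.ndarray  # (N, 2, 2)
    r_draws: np.ndarray  # (N, 2, 2)
    trait_names: tuple
    config: ChainConfig

    @property
    def draws(self) -> pd.DataFrame:
        g, r = self.g_draws, self.r_draws
        return pd.DataFrame({
            "g11": g[:, 0, 0], "g22": g[:, 1, 1], "g12": g[:, 0, 1],
            "r11": r[:, 0, 0], "r22": r[:, 1, 1], "r12": r[:, 0, 1],
            "r_g": g[:, 0, 1] / np.sqrt(g[:, 0, 0] * g[:, 1, 1]),
            "r_e": r[:, 0, 1] / np.sqrt(r[:, 0, 0] * r[:, 1, 1]),
        })


# ---------------------------------------------------------------------------
# numerical kernels

def _sweep_py(indptr, indices, data, diag_pos, rhs, theta, noise, resid_var):
    """One scalar-Gibbs sweep over C theta = rhs; conditional variance
    resid_var / C_jj."""
    for j in range(theta.shape[0]):
        s = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            s += data[k] * theta[indices[k]]
        cjj = data[diag_pos[j]]
        mean = (rhs[j] - s + cjj * theta[j]) / cjj
        theta[j] = mean + noise[j] * math.sqrt(resid_var / cjj)


try:  # optional acceleration; the pure-python kernel is the reference
    from numba import njit

    _sweep = njit(cache=True)(_sweep_py)
except ImportError:  # pragma: no cover
    _sweep = _sweep_py


def sample_scaled_inv_chi2(ss: float, df: float, rng: np.random.Generator) -> float:
    """Draw from the scaled-inverse-chi-square full conditional ss / chi2_df."""
    return ss / rng.chisquare(df)


def _sample_inv_wishart_2x2(df: float, scale: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """IW(df, scale) draw for p=2 via the Bartlett decomposition of the
    Wishart of the inverse scale."""
    s11, s12, s22 = scale[0, 0], scale[0, 1], scale[1, 1]
    det = s11 * s22 - s12 * s12
    if det <= 0 or s11 <= 0:
        raise FloatingPointError("inverse-Wishart scale not positive definite")
    inv = np.array([[s22, -s12], [-s12, s11]]) / det
    L = np.linalg.cholesky(inv)
    A = np.array([[math.sqrt(rng.chisquare(df)), 0.0],
                  [rng.standard_normal(), math.sqrt(rng.chisquare(df - 1.0))]])
    LA = L @ A
    W = LA @ LA.T  # ~ Wishart(df, scale^-1)
    dW = W[0, 0] * W[1, 1] - W[0, 1] * W[1, 0]
    return np.array([[W[1, 1], -W[0, 1]], [-W[0, 1], W[0, 0]]]) / dW


def _csr_positions(P: sparse.csr_matrix, rows: np.ndarray,
                   cols: np.ndarray) -> np.ndarray:
    """Index of each (row, col) entry inside P.data (P must have sorted
    indices and contain every requested entry)."""
    pos = np.empty(len(rows), dtype=np.int64)
    indptr, indices = P.indptr, P.indices
    for k in range(len(rows)):
        lo, hi = indptr[rows[k]], indptr[rows[k] + 1]
        j = lo + np.searchsorted(indices[lo:hi], cols[k])
        if j >= hi or indices[j] != cols[k]:
            raise RuntimeError("pattern entry missing — internal error")
        pos[k] = j
    return pos


def _pattern_union(TT: sparse.csr_matrix, extra_rows, extra_cols) -> sparse.csr_matrix:
    n = TT.shape[0]
    S = sparse.coo_matrix((np.ones(len(extra_rows)), (extra_rows, extra_cols)),
                          shape=(n, n)).tocsr()
    P = (abs(TT) + S).tocsr()
    P.sum_duplicates()
    P.sort_indices()
    return P


class _DivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# univariate chain

def run_chain(records: TraitRecords, ped: PedigreeTable, spec: ModelSpec,
              config: ChainConfig, design: DesignMatrices | None = None,
              use_inbreeding: bool = True) -> PosteriorChain:
    """Run one univariate Gibbs chain and return the retained draws.

    The iteration loop consumes randomness in a fixed order (location noise,
    then genetic, permanent-environment and residual variance draws), so two
    runs with identical seed yield bitwise-identical chains.
    """
    D = design if design is not None else build_design(records, ped, spec)
    y = D.y
    n, p, q, nd = D.n, D.p, D.q, D.n_dams
    has_m, has_pe = spec.has_maternal_genetic, spec.has_maternal_pe
    T = D.stacked()
    TT = (T.T @ T).tocsr()
    Ainv = a_inverse(ped, use_inbreeding=use_inbreeding)
    Ac = Ainv.tocoo()

    off_u = p
    off_d = p + q
    off_pe = p + q + (q if has_m else 0)
    nunk = off_pe + nd

    ex_rows = [Ac.row + off_u]
    ex_cols = [Ac.col + off_u]
    if has_m:
        ex_rows += [Ac.row + off_u, Ac.row + off_d, Ac.row + off_d]
        ex_cols += [Ac.col + off_d, Ac.col + off_u, Ac.col + off_d]
    if has_pe:
        idx = np.arange(nd) + off_pe
        ex_rows.append(idx)
        ex_cols.append(idx)
    P = _pattern_union(TT, np.concatenate(ex_rows), np.concatenate(ex_cols))

    TTc = TT.tocoo()
    tt_pos = _csr_positions(P, TTc.row, TTc.col)
    tt_vals = TTc.data
    auu = _csr_positions(P, Ac.row + off_u, Ac.col + off_u)
    if has_m:
        aud = _csr_positions(P, Ac.row + off_u, Ac.col + off_d)
        adu = _csr_positions(P, Ac.row + off_d, Ac.col + off_u)
        add = _csr_positions(P, Ac.row + off_d, Ac.col + off_d)
    if has_pe:
        pe_pos = _csr_positions(P, np.arange(nd) + off_pe, np.arange(nd) + off_pe)
    diag_pos = _csr_positions(P, np.arange(nunk), np.arange(nunk))
    indptr, indices = P.indptr, P.indices
    data = np.zeros(P.nnz)
    rhs = np.asarray(T.T @ y).ravel()

    # starting values: equal apportioning of the sample phenotypic variance
    var_y = float(np.var(y, ddof=1))
    n_comp = 2 + has_m + has_pe
    s2a = var_y / n_comp
    s2m = var_y / n_comp if has_m else 0.0
    sam = 0.0
    s2pe = var_y / n_comp if has_pe else 0.0
    s2e = var_y / n_comp
    df0, sc0, dfg, psi_g = config.priors.resolve(var_y, n_comp)

    rng = np.random.default_rng(config.seed)
    theta = np.zeros(nunk)
    n_ret = config.n_retained
    out = np.zeros((n_ret, 5))
    dev_trace = np.zeros(n_ret)
    fitted_sum = np.zeros(n)
    kept = 0

    for it in range(1, config.n_iterations + 1):
        # (1) assemble C = T'T + sigma2_e * Sigma* on the fixed pattern
        data[:] = 0.0
        data[tt_pos] += tt_vals
        if has_m:
            detg = s2a * s2m - sam * sam
            data[auu] += s2e * (s2m / detg) * Ac.data
            data[aud] += s2e * (-sam / detg) * Ac.data
            data[adu] += s2e * (-sam / detg) * Ac.data
            data[add] += s2e * (s2a / detg) * Ac.data
        else:
            data[auu] += (s2e / s2a) * Ac.data
        if has_pe:
            data[pe_pos] += s2e / s2pe

        # (2) scalar Gibbs sweep over all location effects
        noise = rng.standard_normal(nunk)
        _sweep(indptr, indices, data, diag_pos, rhs, theta, noise, s2e)

        fitted = T @ theta
        e = y - fitted

        # (3) genetic (co)variance
        u = theta[off_u:off_u + q]
        Au = Ainv @ u
        suu = float(u @ Au)
        if has_m:
            d = theta[off_d:off_d + q]
            Ad = Ainv @ d
            scale = np.array([[suu, float(u @ Ad)],
                              [float(u @ Ad), float(d @ Ad)]]) + psi_g
            for attempt in range(10):
                G0 = _sample_inv_wishart_2x2(q + dfg, scale, rng)
                if G0[0, 0] > 0 and np.linalg.det(G0) > 0:
                    break
            else:
                raise _DivergenceError(
                    "could not draw a positive-definite genetic covariance; "
                    f"scale={scale.tolist()}")
            s2a, s2m, sam = G0[0, 0], G0[1, 1], G0[0, 1]
        else:
            s2a = sample_scaled_inv_chi2(suu + sc0, q + df0, rng)

        # (4) permanent environment, (5) residual
        if has_pe:
            pe = theta[off_pe:]
            s2pe = sample_scaled_inv_chi2(float(pe @ pe) + sc0, nd + df0, rng)
        sse = float(e @ e)
        s2e = sample_scaled_inv_chi2(sse + sc0, n + df0, rng)

        if not np.isfinite(s2e) or s2e > 1e12 * var_y:
            raise _DivergenceError(
                f"residual variance diverged at iteration {it}: "
                f"sigma2_e={s2e:g}, last draws:\n{out[max(0, kept - 5):kept]}")

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            out[kept] = (s2a, s2m, sam, s2pe, s2e)
            dev_trace[kept] = n * math.log(2.0 * math.pi * s2e) + sse / s2e
            fitted_sum += fitted
            kept += 1

    draws = pd.DataFrame(out[:kept], columns=_PARAM_ORDER)
    draws["deviance"] = dev_trace[:kept]
    return PosteriorChain(
        draws=draws, model=spec, config=config, n_records=n, y=y,
        mean_fitted=fitted_sum / max(kept, 1), trait_name=records.trait_name,
        n_excluded=D.n_excluded,
        record_key=tuple(np.sort(D.Z.tocoo().col + 1)))


# ---------------------------------------------------------------------------
# bivariate chain

def run_bivariate_chain(records_pair, ped: PedigreeTable, config: ChainConfig,
                        use_inbreeding: bool = True) -> BivariateChain:
    """Bivariate (direct-additive) chain for genetic/environmental correlations.

    Traits are canonically ordered by name internally and the output is
    transposed back to the caller's order, so exchanging the two traits
    yields exactly transposed covariance draws for the same seed.
    """
    ra, rb = records_pair
    swapped = ra.trait_name > rb.trait_name
    if swapped:
        ra, rb = rb, ra
    chain = _bivariate_core(ra, rb, ped, config, use_inbreeding)
    if swapped:
        chain = BivariateChain(
            g_draws=chain.g_draws[:, ::-1, ::-1].copy(),
            r_draws=chain.r_draws[:, ::-1, ::-1].copy(),
            trait_names=(chain.trait_names[1], chain.trait_names[0]),
            config=config)
    return chain


def _trait_design(rec: TraitRecords, animals: np.ndarray):
    """Row-aligned (over `animals`) fixed-effect matrix, observation vector
    and missingness mask for one trait."""
    df = rec.data.set_index("animal")
    obs = np.array([a in df.index for a in animals])
    if not obs.any():
        raise ValueError(f"trait {rec.trait_name!r} has no records")
    m = len(animals)
    y = np.zeros(m)
    y[obs] = df.loc[animals[obs], "value"].to_numpy(dtype=float)
    # reference coding from observed levels; unseen levels fold into the
    # reference (affects only the imputation mean of missing records)
    cols: list[np.ndarray] = [np.ones(m)]
    for factor in ("generation", "hatch"):
        obs_levels = np.unique(df[factor])
        lev = np.full(m, obs_levels[0], dtype=object)
        lev[obs] = df.loc[animals[obs], factor].to_numpy()
        for c in obs_levels[1:]:
            col = (lev == c).astype(float)
            cols.append(col)
    X = sparse.csr_matrix(np.column_stack(cols))
    return X, y, obs


def _bivariate_core(ra, rb, ped, config, use_inbreeding):
    q = ped.q
    animals = np.unique(np.concatenate([ra.data["animal"].to_numpy(),
                                        rb.data["animal"].to_numpy()])).astype(int)
    m = len(animals)
    Xa, ya, obs_a = _trait_design(ra, animals)
    Xb, yb, obs_b = _trait_design(rb, animals)
    Z = sparse.csr_matrix((np.ones(m), (np.arange(m), animals - 1)), shape=(m, q))
    Ta = sparse.hstack([Xa, Z], format="csr")
    Tb = sparse.hstack([Xb, Z], format="csr")
    pa, pb = Xa.shape[1], Xb.shape[1]
    na, nb = pa + q, pb + q
    nunk = na + nb

    Ainv = a_inverse(ped, use_inbreeding=use_inbreeding)
    Ac = Ainv.tocoo()
    TTaa = (Ta.T @ Ta).tocoo()
    TTab = (Ta.T @ Tb).tocoo()
    TTbb = (Tb.T @ Tb).tocoo()

    blocks_rows = [TTaa.row, TTab.row, TTab.col + na, TTbb.row + na,
                   Ac.row + pa, Ac.row + pa, Ac.row + na + pb, Ac.row + na + pb]
    blocks_cols = [TTaa.col, TTab.col + na, TTab.row, TTbb.col + na,
                   Ac.col + pa, Ac.col + na + pb, Ac.col + pa, Ac.col + na + pb]
    P = _pattern_union(sparse.csr_matrix((nunk, nunk)),
                       np.concatenate(blocks_rows), np.concatenate(blocks_cols))
    pos = {
        "aa": _csr_positions(P, TTaa.row, TTaa.col),
        "ab": _csr_positions(P, TTab.row, TTab.col + na),
        "ba": _csr_positions(P, TTab.col + na, TTab.row),
        "bb": _csr_positions(P, TTbb.row + na, TTbb.col + na),
        "g11": _csr_positions(P, Ac.row + pa, Ac.col + pa),
        "g12": _csr_positions(P, Ac.row + pa, Ac.col + na + pb),
        "g21": _csr_positions(P, Ac.row + na + pb, Ac.col + pa),
        "g22": _csr_positions(P, Ac.row + na + pb, Ac.col + na + pb),
    }
    diag_pos = _csr_positions(P, np.arange(nunk), np.arange(nunk))
    indptr, indices = P.indptr, P.indices
    data = np.zeros(P.nnz)

    va, vb = float(np.var(ya[obs_a], ddof=1)), float(np.var(yb[obs_b], ddof=1))
    G0 = np.diag([va / 2, vb / 2])
    R0 = np.diag([va / 2, vb / 2])
    _, _, dfg, _ = config.priors.resolve(1.0, 2)  # df only; scale built below
    if config.priors.mode == "flat":
        psi_g = psi_r = np.zeros((2, 2))
    else:
        psi_g = np.diag([0.25 * va, 0.25 * vb])
        psi_r = np.diag([0.25 * va, 0.25 * vb])

    rng = np.random.default_rng(config.seed)
    theta = np.zeros(nunk)
    ycur = np.stack([ya.copy(), yb.copy()])
    obs = np.stack([obs_a, obs_b])
    n_ret = config.n_retained
    g_draws = np.zeros((n_ret, 2, 2))
    r_draws = np.zeros((n_ret, 2, 2))
    kept = 0

    def inv2(Mx):
        det = Mx[0, 0] * Mx[1, 1] - Mx[0, 1] * Mx[1, 0]
        return np.array([[Mx[1, 1], -Mx[0, 1]], [-Mx[0, 1], Mx[0, 0]]]) / det

    for it in range(1, config.n_iterations + 1):
        fa = Ta @ theta[:na]
        fb = Tb @ theta[na:]
        fit = np.stack([fa, fb])

        # (1) impute residuals of single-trait records (data augmentation)
        for t, o in ((0, 1), (1, 0)):
            miss = obs[o] & ~obs[t]
            if miss.any():
                e_obs = ycur[o][miss] - fit[o][miss]
                mu = R0[t, o] / R0[o, o] * e_obs
                sd = math.sqrt(max(R0[t, t] - R0[t, o] ** 2 / R0[o, o], 1e-30))
                ycur[t][miss] = fit[t][miss] + mu + sd * rng.standard_normal(miss.sum())

        # (2) location sweep under current R0, G0
        Rinv = inv2(R0)
        Ginv = inv2(G0)
        data[:] = 0.0
        data[pos["aa"]] += Rinv[0, 0] * TTaa.data
        data[pos["ab"]] += Rinv[0, 1] * TTab.data
        data[pos["ba"]] += Rinv[0, 1] * TTab.data
        data[pos["bb"]] += Rinv[1, 1] * TTbb.data
        data[pos["g11"]] += Ginv[0, 0] * Ac.data
        data[pos["g12"]] += Ginv[0, 1] * Ac.data
        data[pos["g21"]] += Ginv[0, 1] * Ac.data
        data[pos["g22"]] += Ginv[1, 1] * Ac.data
        ta_y = Ta.T @ ycur[0]
        tb_y = Tb.T @ ycur[1]
        rhs = np.concatenate([Rinv[0, 0] * ta_y + Rinv[0, 1] * (Ta.T @ ycur[1]),
                              Rinv[0, 1] * (Tb.T @ ycur[0]) + Rinv[1, 1] * tb_y])
        noise = rng.standard_normal(nunk)
        _sweep(indptr, indices, data, diag_pos, rhs, theta, noise, 1.0)

        # (3) G0 from breeding values, (4) R0 from complete residuals
        U = np.column_stack([theta[pa:na], theta[na + pb:]])
        AU = Ainv @ U
        SG = U.T @ AU + psi_g
        G0 = _sample_inv_wishart_2x2(q + dfg, SG, rng)
        E = np.column_stack([ycur[0] - Ta @ theta[:na], ycur[1] - Tb @ theta[na:]])
        SR = E.T @ E + psi_r
        R0 = _sample_inv_wishart_2x2(m + dfg, SR, rng)
        if not np.isfinite(R0).all():
            raise _DivergenceError(f"residual covariance diverged at iteration {it}")

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            g_draws[kept] = G0
            r_draws[kept] = R0
            kept += 1

    return BivariateChain(g_draws=g_draws[:kept], r_draws=r_draws[:kept],
                          trait_names=(ra.trait_name, rb.trait_name),
                          config=config)
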