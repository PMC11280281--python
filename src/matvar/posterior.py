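"""Posterior summaries, derived genetic parameters and convergence checks.

The quantities reported for each trait x model are posterior means,
posterior standard deviations and 95% highest-posterior-density intervals
(HPDI) of the variance components and of the derived ratios

    h2_additive = sigma2_a / sigma2_p
    h2_maternal = sigma2_m / sigma2_p
    c2_mpe      = sigma2_pe / sigma2_p

with phenotypic variance sigma2_p = sigma2_a + sigma2_m + sigma_am +
sigma2_pe + sigma2_e (terms present per model).  The direct-maternal
covariance is INCLUDED in sigma2_p by default; the exclusive convention is
available behind a flag.  Ratios are computed per draw and then summarized;
the ratio of posterior means is reported alongside as a cross-check.

Convergence diagnostics follow common MCMC practice: a Geweke z comparing
the first 10% against the last 50% of the chain with spectral-density
variance estimates, effective sample size from the integrated
autocorrelation time, and lag autocorrelations for trace inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import PosteriorChain, VarianceState

__all__ = ["GeneticSummary", "derived_ratios", "hpdi", "summarize",
           "diagnostics", "effective_sample_size", "geweke_z", "autocorrelation"]


def derived_ratios(state: VarianceState, include_covariance: bool = True):
    """(h2_additive, h2_maternal, c2_mpe, sigma2_p) for one variance draw.

    Raises if sigma2_p is non-positive (callers exclude and count such
    draws).
    """
    s2p = (state.sigma2_a + state.sigma2_m + state.sigma2_pe + state.sigma2_e
           + (state.sigma_am if include_covariance else 0.0))
    if s2p <= 0:
        raise ValueError(f"non-positive phenotypic variance {s2p:g}")
    return (state.sigma2_a / s2p, state.sigma2_m / s2p,
            state.sigma2_pe / s2p, s2p)


def hpdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over the sorted draws containing
    ceil(level * N) of them; ties break toward the lower start index."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    k = min(int(math.ceil(level * n)), n)
    if k < 2:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) minimizer
    return float(x[i]), float(x[i + k - 1])


@dataclass
class GeneticSummary:
    """Posterior mean / SD / HPDI per parameter plus diagnostics.

    ``table`` rows are parameters (variance components and derived ratios);
    ``n_flagged`` counts draws excluded from ratio summaries because their
    phenotypic variance was non-positive; ``ratio_of_means`` is the
    plug-in cross-check h2 computed from posterior-mean components.
    """

    trait_name: str
    model_id: str
    table: pd.DataFrame
    level: float
    n_draws: int
    n_flagged: int = 0
    ratio_of_means: dict = field(default_factory=dict)
    dic: float | None = None

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]


def _ratio_frame(draws: pd.DataFrame, include_covariance: bool):
    s2p = (draws["sigma2_a"] + draws["sigma2_m"] + draws["sigma2_pe"]
           + draws["sigma2_e"]
           + (draws["sigma_am"] if include_covariance else 0.0))
    ok = s2p > 0
    out = pd.DataFrame({
        "h2_additive": draws["sigma2_a"] / s2p,
        "h2_maternal": draws["sigma2_m"] / s2p,
        "c2_mpe": draws["sigma2_pe"] / s2p,
        "sigma2_p": s2p,
    })[ok]
    return out, int((~ok).sum())


def summarize(chain: PosteriorChain, level: float = 0.95,
              include_covariance: bool = True) -> GeneticSummary:
    """Posterior mean, SD and HPDI for components and derived ratios."""
    draws = chain.draws
    if len(draws) < 100:
        raise ValueError(f"need >= 100 retained draws, got {len(draws)}")
    spec = chain.model
    params = ["sigma2_a", "sigma2_e"]
    if spec.has_maternal_genetic:
        params = ["sigma2_a", "sigma2_m", "sigma_am"] + (
            ["sigma2_pe"] if spec.has_maternal_pe else []) + ["sigma2_e"]
    ratios, n_flagged = _ratio_frame(draws, include_covariance)
    cols = {p: draws[p] for p in params}
    cols["h2_additive"] = ratios["h2_additive"]
    if spec.has_maternal_genetic:
        cols["h2_maternal"] = ratios["h2_maternal"]
    if spec.has_maternal_pe:
        cols["c2_mpe"] = ratios["c2_mpe"]
    cols["sigma2_p"] = ratios["sigma2_p"]

    rows = []
    for name, x in cols.items():
        lo, hi = hpdi(x.to_numpy(), level)
        rows.append({"parameter": name, "posterior_mean": float(x.mean()),
                     "posterior_sd": float(x.std(ddof=1)),
                     "hpdi_low": lo, "hpdi_high": hi})
    table = pd.DataFrame(rows).set_index("parameter")

    mean_state = VarianceState(*(float(draws[p].mean()) for p in
                                 ["sigma2_a", "sigma2_m", "sigma_am",
                                  "sigma2_pe", "sigma2_e"]))
    h2a, h2m, c2, _ = derived_ratios(mean_state, include_covariance)
    return GeneticSummary(
        trait_name=chain.trait_name, model_id=spec.model_id, table=table,
        level=level, n_draws=len(draws), n_flagged=n_flagged,
        ratio_of_means={"h2_additive": h2a, "h2_maternal": h2m, "c2_mpe": c2})


# ---------------------------------------------------------------------------
# convergence diagnostics

def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations at lags 0..max_lag (FFT-based)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1] / n
    if acov[0] <= 0:
        return np.r_[1.0, np.zeros(max_lag)]
    return acov / acov[0]


def effective_sample_size(x: np.ndarray) -> float:
    """ESS = N / (1 + 2 sum rho_k) with Geyer's initial-monotone truncation
    of paired autocorrelation sums."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        return float(n)
    rho = autocorrelation(x, min(n - 2, n // 2))
    # pair consecutive lags (1,2), (3,4), ...; stop at first non-positive,
    # enforce monotone decrease
    pair_sums = []
    k = 1
    while k + 1 < len(rho):
        s = rho[k] + rho[k + 1]
        if s <= 0:
            break
        pair_sums.append(s)
        k += 2
    for i in range(1, len(pair_sums)):
        pair_sums[i] = min(pair_sums[i], pair_sums[i - 1])
    tau = 1.0 + 2.0 * float(np.sum(pair_sums))
    return float(min(n, n / tau))


def _spectral_density_zero(x: np.ndarray) -> float:
    """S(0) estimate via Bartlett-windowed autocovariances."""
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return float(np.var(x))
    K = max(1, int(math.sqrt(n)))
    rho = autocorrelation(x, K)
    var = float(np.var(x))
    w = 1.0 - np.arange(1, K + 1) / (K + 1)
    return var * (1.0 + 2.0 * float(np.sum(w * rho[1:K + 1])))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: difference of early/late segment means scaled
    by their spectral-density standard errors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    va = _spectral_density_zero(a) / len(a)
    vb = _spectral_density_zero(b) / len(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def diagnostics(chain: PosteriorChain | pd.DataFrame, max_lag: int = 20) -> pd.DataFrame:
    """Per-parameter Geweke z, ESS and lag-1..max_lag autocorrelations."""
    draws = chain.draws if isinstance(chain, PosteriorChain) else chain
    if len(draws) < 200:
        raise ValueError(f"need >= 200 retained draws, got {len(draws)}")
    rows = {}
    for name, x in draws.items():
        x = x.to_numpy(dtype=float)
        if not np.isfinite(x).all():
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise ValueError(f"non-finite draw for {name!r} at index {bad}")
        if np.ptp(x) == 0:  # constant column (component absent from model)
            continue
        rho = autocorrelation(x, max_lag)
        rows[name] = {
            "geweke_z": geweke_z(x),
            "ess": effective_sample_size(x),
            **{f"acf_lag{k}": rho[k] for k in range(1, max_lag + 1)},
        }
    return pd.DataFrame(rows).T
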