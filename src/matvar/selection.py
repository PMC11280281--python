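"""DIC computation and lowest-DIC model selection.

The deviance information criterion used here is the conditional one:
per-draw deviance D = -2 log N(y | location fit, I sigma2_e) is averaged
over the retained draws (Dbar), the plug-in deviance D(theta_bar) is
evaluated at the posterior means of the location fit and of sigma2_e, and

    pD  = Dbar - D(theta_bar)        (effective number of parameters)
    DIC = Dbar + pD = 2 Dbar - D(theta_bar)

The model with the lowest DIC is selected; a difference below a small
threshold is reported as a tie and the simpler model preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MODELS
from .gibbs import PosteriorChain

__all__ = ["ModelComparison", "dic", "select_best", "compare_models"]

TIE_THRESHOLD = 0.5

_COMPLEXITY = {mid: MODELS[mid].complexity for mid in MODELS}


@dataclass
class ModelComparison:
    """DIC decomposition for one fitted model."""

    model_id: str
    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd

    @property
    def pd_negative(self) -> bool:
        return self.pd < 0


def dic(chain: PosteriorChain) -> ModelComparison:
    """Conditional DIC from a chain's deviance trace and posterior-mean fit."""
    if "deviance" not in chain.draws:
        raise ValueError("chain carries no deviance trace")
    dbar = float(chain.draws["deviance"].mean())
    s2e = chain.mean_sigma2_e
    resid = chain.y - chain.mean_fitted
    n = chain.n_records
    d_hat = n * math.log(2.0 * math.pi * s2e) + float(resid @ resid) / s2e
    return ModelComparison(chain.model.model_id, dbar=dbar, d_at_mean=d_hat)


def select_best(comparisons, dic_values: dict | None = None,
                record_keys: dict | None = None) -> tuple[str, bool]:
    """Pick the lowest-DIC model; return ``(model_id, tie_flag)``.

    ``comparisons`` is a list of :class:`ModelComparison` or a mapping
    ``model_id -> DIC value``.  Ties (|dDIC| < 0.5) go to the simpler model.
    If ``record_keys`` (model_id -> identifier of the fitted record subset)
    is given, differing subsets raise: DICs computed on different data are
    not comparable.
    """
    if dic_values is None:
        dic_values = {c.model_id: c.dic for c in comparisons}
    if not dic_values:
        raise ValueError("no models to compare")
    if record_keys is not None and len(set(record_keys.values())) > 1:
        raise ValueError(
            "models were fitted to different record subsets; DIC is not "
            "comparable (records with unknown dams are excluded under "
            "maternal models)")
    items = sorted(dic_values.items(),
                   key=lambda kv: (kv[1], _COMPLEXITY.get(kv[0], 99)))
    best_id, best_dic = items[0]
    tie = any(abs(v - best_dic) < TIE_THRESHOLD and mid != best_id
              for mid, v in items[1:])
    if tie:
        tied = [mid for mid, v in items if abs(v - best_dic) < TIE_THRESHOLD]
        best_id = min(tied, key=lambda mid: _COMPLEXITY.get(mid, 99))
    return best_id, tie


def compare_models(chains: dict[str, PosteriorChain]) -> pd.DataFrame:
    """DIC table for several models fitted to the same trait records."""
    keys = {mid: ch.record_key for mid, ch in chains.items()}
    comps = {mid: dic(ch) for mid, ch in chains.items()}
    best, tie = select_best(None, {m: c.dic for m, c in comps.items()},
                            record_keys=keys)
    rows = []
    for mid, c in comps.items():
        rows.append({"model": mid, "dbar": c.dbar, "d_at_mean": c.d_at_mean,
                     "pd": c.pd, "dic": c.dic, "best": mid == best,
                     "tie": tie and mid == best,
                     "pd_negative": c.pd_negative})
    return pd.DataFrame(rows).set_index("model").sort_index()
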