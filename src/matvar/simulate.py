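"""Synthetic pedigreed populations with direct and maternal effects.

The generator emulates a closed layer flock regenerated by pedigreed
full-sib-design matings: a base of unrelated sires and dams (default 50
sires x 250 dams at a 1:5 mating ratio), followed by discrete generations
(default 3) in which each dam produces a fixed number of recorded female
progeny, assigned uniformly to hatches (default 5) within generation.
Parents of the next generation are drawn at random from the previous one
(no index selection, which would bias variance-recovery checks).

Phenotypes follow the generative law of the full maternal model:

    y = intercept + generation effect + hatch effect + u_animal + d_dam
        + pe_dam + e

with founder (u, d) ~ N2(0, [[s2a, sam], [sam, s2m]]), offspring
(u, d) = midparent + Mendelian sampling term of covariance
(1/2)(1 - (F_s + F_d)/2) G0, dam pe ~ N(0, s2pe) and e ~ N(0, s2e).
Setting s2m = sam = s2pe = 0 reduces to the direct-additive model.
Fixed-effect levels default to steps of half a phenotypic SD, so a model
that ignored them would be detectably wrong.

A multi-trait variant shares one pedigree across traits and, when genetic
and residual correlation matrices are supplied, generates correlated
direct-additive traits for bivariate analyses.

Every sampled effect is kept in a truth manifest so downstream estimation
error can be computed without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import PedigreeTable
from .qc import TraitRecords

__all__ = ["SimulationConfig", "TraitParams", "simulate_population",
           "simulate_flock", "simulate_correlated_traits", "apply_missingness"]


@dataclass(frozen=True)
class TraitParams:
    """Generating variance components and mean structure for one trait."""

    name: str = "trait"
    sigma2_a: float = 25.0
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_pe: float = 0.0
    sigma2_e: float = 60.0
    intercept: float = 100.0
    generation_effects: tuple | None = None
    hatch_effects: tuple | None = None

    def __post_init__(self):
        for nm in ("sigma2_a", "sigma2_m", "sigma2_pe", "sigma2_e"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if self.sigma2_m > 0:
            if self.sigma2_a * self.sigma2_m - self.sigma_am ** 2 <= 0:
                raise ValueError(
                    "direct-maternal covariance matrix not positive definite")
        elif self.sigma_am != 0:
            raise ValueError("sigma_am requires sigma2_m > 0")

    @property
    def g0(self) -> np.ndarray:
        return np.array([[self.sigma2_a, self.sigma_am],
                         [self.sigma_am, self.sigma2_m]])

    @property
    def phenotypic_sd(self) -> float:
        return float(np.sqrt(self.sigma2_a + self.sigma2_m + self.sigma_am
                             + self.sigma2_pe + self.sigma2_e))

    def true_components(self) -> dict:
        return {"sigma2_a": self.sigma2_a, "sigma2_m": self.sigma2_m,
                "sigma_am": self.sigma_am, "sigma2_pe": self.sigma2_pe,
                "sigma2_e": self.sigma2_e}

    def fixed_levels(self, n_generations: int, n_hatches: int):
        sd = self.phenotypic_sd

        def default(k):
            return (np.arange(k) - (k - 1) / 2) * 0.5 * sd

        g = (np.asarray(self.generation_effects, dtype=float)
             if self.generation_effects is not None else default(n_generations))
        h = (np.asarray(self.hatch_effects, dtype=float)
             if self.hatch_effects is not None else default(n_hatches))
        if len(g) != n_generations or len(h) != n_hatches:
            raise ValueError("fixed-effect level vectors have wrong length")
        return g, h


@dataclass(frozen=True)
class SimulationConfig(TraitParams):
    """Study design (mating structure) plus one trait's parameters.

    ``n_dams`` defaults to ``n_sires * mating_ratio``.
    """

    n_sires: int = 50
    mating_ratio: int = 5
    n_dams: int | None = None
    n_generations: int = 3
    n_hatches: int = 5
    progeny_per_dam: int = 2
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self):
        super().__post_init__()
        if self.n_dams is None:
            object.__setattr__(self, "n_dams", self.n_sires * self.mating_ratio)
        object.__setattr__(self, "name", self.trait_name)

    def params(self) -> TraitParams:
        return TraitParams(
            name=self.trait_name, sigma2_a=self.sigma2_a, sigma2_m=self.sigma2_m,
            sigma_am=self.sigma_am, sigma2_pe=self.sigma2_pe,
            sigma2_e=self.sigma2_e, intercept=self.intercept,
            generation_effects=self.generation_effects,
            hatch_effects=self.hatch_effects)


# ---------------------------------------------------------------------------
# pedigree structure

def _pedigree_structure(cfg, rng: np.random.Generator):
    """Mating structure only: pedigree plus (animal, dam, generation, hatch)
    rows for every recorded progeny."""
    ns, ndm = cfg.n_sires, cfg.n_dams
    sire_col: list[int] = []
    dam_col: list[int] = []

    def new_animal(s, d):
        sire_col.append(s)
        dam_col.append(d)
        return len(sire_col)  # 1-based id

    sires = [new_animal(0, 0) for _ in range(ns)]
    dams = [new_animal(0, 0) for _ in range(ndm)]

    recorded: list[tuple[int, int, int, int]] = []
    for g in range(1, cfg.n_generations + 1):
        offspring = []
        for j, dam in enumerate(dams):
            sire = sires[j % ns]  # fixed 1:ratio assignment, full sibs per dam
            hatch = int(rng.integers(cfg.n_hatches)) + 1
            for _ in range(cfg.progeny_per_dam):
                a = new_animal(sire, dam)
                offspring.append(a)
                recorded.append((a, dam, g, hatch))
        if g < cfg.n_generations:
            picks = rng.choice(len(offspring), size=ns + ndm, replace=True)
            sires = [offspring[i] for i in picks[:ns]]
            dams = [offspring[i] for i in picks[ns:]]

    ped = PedigreeTable(sire=np.array(sire_col), dam=np.array(dam_col),
                        labels=list(range(1, len(sire_col) + 1)))
    ped.f()
    return ped, recorded


def _sample_breeding_values(ped: PedigreeTable, g0: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Per-animal effect vectors down the pedigree: founders from N(0, G0),
    offspring from midparent plus inbreeding-shrunk Mendelian sampling."""
    q = ped.q
    t = g0.shape[0]
    F = ped.f()
    eye = 1e-12 * np.eye(t)
    chol0 = np.linalg.cholesky(g0 + eye)
    out = np.zeros((q, t))
    chol_cache: dict[float, np.ndarray] = {}
    for i in range(q):
        s, d = ped.sire[i], ped.dam[i]
        z = rng.standard_normal(t)
        if s == 0 and d == 0:
            out[i] = chol0 @ z
        else:
            shrink = 0.5 * (1.0 - 0.5 * (F[s - 1] + F[d - 1]))
            L = chol_cache.get(shrink)
            if L is None:
                L = np.linalg.cholesky(shrink * g0 + eye)
                chol_cache[shrink] = L
            out[i] = 0.5 * (out[s - 1] + out[d - 1]) + L @ z
    return out


def _sample_trait(ped, recorded, params: TraitParams, n_generations: int,
                  n_hatches: int, rng: np.random.Generator):
    gen_eff, hatch_eff = params.fixed_levels(n_generations, n_hatches)
    ud = _sample_breeding_values(ped, params.g0, rng)
    pe = np.zeros(ped.q)
    if params.sigma2_pe > 0:
        for d in sorted({r[1] for r in recorded}):
            pe[d - 1] = np.sqrt(params.sigma2_pe) * rng.standard_normal()
    resid = np.sqrt(params.sigma2_e) * rng.standard_normal(len(recorded))
    rows = []
    for k, (a, d, g, h) in enumerate(recorded):
        value = (params.intercept + gen_eff[g - 1] + hatch_eff[h - 1]
                 + ud[a - 1, 0] + ud[d - 1, 1] + pe[d - 1] + resid[k])
        rows.append({"animal": a, "dam": d, "generation": g, "hatch": h,
                     "value": value})
    records = TraitRecords(params.name, pd.DataFrame(rows))
    truth = {"true_components": params.true_components(),
             "u": ud[:, 0].copy(), "d": ud[:, 1].copy(), "pe": pe.copy(),
             "residuals": resid, "generation_effects": gen_eff,
             "hatch_effects": hatch_eff, "intercept": params.intercept}
    return records, truth


def simulate_population(config: SimulationConfig):
    """Simulate pedigree, one trait's records and a truth manifest."""
    rng = np.random.default_rng(config.seed)
    ped, recorded = _pedigree_structure(config, rng)
    records, truth = _sample_trait(ped, recorded, config.params(),
                                   config.n_generations, config.n_hatches, rng)
    truth["config"] = config
    truth["inbreeding"] = ped.f().copy()
    return ped, records, truth


def simulate_flock(design: SimulationConfig, traits: list[TraitParams],
                   seed: int | None = None):
    """One pedigree, several independently sampled traits.

    Returns ``(ped, {name: TraitRecords}, manifest)``; trait effects are
    drawn independently (use :func:`simulate_correlated_traits` for
    genetically correlated traits).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ped, recorded = _pedigree_structure(design, rng)
    all_records: dict[str, TraitRecords] = {}
    manifest = {"design": design, "traits": {}, "inbreeding": ped.f().copy()}
    for tp in traits:
        rec, truth = _sample_trait(ped, recorded, tp, design.n_generations,
                                   design.n_hatches, rng)
        all_records[tp.name] = rec
        manifest["traits"][tp.name] = truth
    return ped, all_records, manifest


def simulate_correlated_traits(design: SimulationConfig, g0: np.ndarray,
                               r0: np.ndarray, trait_names: list[str],
                               intercepts=None, seed: int | None = None):
    """Direct-additive traits with genetic covariance ``g0`` and residual
    covariance ``r0`` on one shared pedigree.

    Used to study genetic/environmental correlations; maternal effects are
    not part of this generative mode.  Returns
    ``(ped, {name: TraitRecords}, manifest)``.
    """
    g0 = np.asarray(g0, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    t = len(trait_names)
    for nm, M in (("genetic", g0), ("residual", r0)):
        if M.shape != (t, t):
            raise ValueError(f"{nm} covariance must be {t}x{t}")
        if np.linalg.eigvalsh(M).min() <= 0:
            raise ValueError(f"{nm} covariance not positive definite")
    if intercepts is None:
        intercepts = [100.0] * t
    rng = np.random.default_rng(design.seed if seed is None else seed)
    ped, recorded = _pedigree_structure(design, rng)
    U = _sample_breeding_values(ped, g0, rng)
    E = rng.multivariate_normal(np.zeros(t), r0, size=len(recorded),
                                method="cholesky")
    sds = np.sqrt(np.diag(g0) + np.diag(r0))
    out: dict[str, TraitRecords] = {}
    for j, name in enumerate(trait_names):
        gen_eff = (np.arange(design.n_generations)
                   - (design.n_generations - 1) / 2) * 0.5 * sds[j]
        hat_eff = (np.arange(design.n_hatches)
                   - (design.n_hatches - 1) / 2) * 0.5 * sds[j]
        rows = []
        for k, (a, d, g, h) in enumerate(recorded):
            rows.append({"animal": a, "dam": d, "generation": g, "hatch": h,
                         "value": intercepts[j] + gen_eff[g - 1] + hat_eff[h - 1]
                         + U[a - 1, j] + E[k, j]})
        out[name] = TraitRecords(name, pd.DataFrame(rows))
    manifest = {"design": design, "g0": g0, "r0": r0, "u": U.copy(),
                "trait_names": list(trait_names),
                "inbreeding": ped.f().copy()}
    return ped, out, manifest


def apply_missingness(records: TraitRecords, keep_fraction: float = 1.0,
                      seed: int = 0,
                      drop_generations: tuple = ()) -> TraitRecords:
    """Random per-record thinning plus optional whole-generation blanking.

    Emulates trait-specific record counts (and traits recorded in a subset
    of generations only).  ``keep_fraction`` must lie in (0, 1].
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    df = records.data
    if drop_generations:
        df = df[~df["generation"].isin(list(drop_generations))]
    if keep_fraction < 1.0:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(df)) < keep_fraction
        df = df[keep]
    return replace(records, data=df.reset_index(drop=True))
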