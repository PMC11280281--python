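"""Trait-record screening and descriptive statistics.

Records are screened once per trait with a mean +/- 3 SD rule (mean and SD
taken from the full input, no re-estimation after removal), and summarized
as n, mean, SE, SD and CV% in the layout conventional for flock data
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["TraitRecords", "filter_outliers", "describe", "load_phenotypes"]

#: columns every record table carries
RECORD_COLUMNS = ["animal", "dam", "generation", "hatch", "value"]


@dataclass
class TraitRecords:
    """Phenotype records for one trait.

    ``data`` holds one row per animal with columns
    ``animal, dam, generation, hatch, value``; dam 0 means unknown.
    Missing observations are absent rows, never sentinel values.
    """

    trait_name: str
    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"records for {self.trait_name!r} missing columns {missing}")
        if self.data["animal"].duplicated().any():
            dup = self.data.loc[self.data["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(
                f"animal {dup} has more than one {self.trait_name!r} record "
                "(single-record-per-animal design)")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    def validate_against_pedigree(self, ped) -> None:
        ids = set(range(1, ped.q + 1))
        bad = set(self.data["animal"]) - ids
        if bad:
            raise ValueError(
                f"{len(bad)} {self.trait_name!r} records reference animals absent "
                f"from the pedigree (e.g. {sorted(bad)[:3]})")


def filter_outliers(records: TraitRecords, k: float = 3.0,
                    within_cells: bool = False) -> tuple[TraitRecords, TraitRecords]:
    """Retain records with |value - mean| <= k * SD (single pass).

    Mean and SD are computed once on the full input; no iterative
    re-screening.  With ``within_cells=True`` the rule is applied separately
    inside each generation x hatch cell instead of over the whole trait.
    Returns ``(retained, removed)``; removed rows carry a ``reason`` column.
    """
    df = records.data
    if len(df) < 2:
        raise ValueError("outlier screening needs at least 2 records")

    def _mask(values: pd.Series) -> pd.Series:
        mu = values.mean()
        sd = values.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"{records.trait_name}: zero variance, nothing screened", stacklevel=2)
            return pd.Series(True, index=values.index)
        return (values - mu).abs() <= k * sd

    if within_cells:
        keep = df.groupby(["generation", "hatch"], group_keys=False)["value"].apply(_mask)
        keep = keep.reindex(df.index)
    else:
        keep = _mask(df["value"])
    retained = replace(records, data=df[keep].reset_index(drop=True))
    removed_df = df[~keep].copy()
    mu, sd = df["value"].mean(), df["value"].std(ddof=1)
    removed_df["reason"] = [
        f"value {v:g} outside mean+/-{k:g}SD ({mu:g}+/-{k * sd:g})"
        for v in removed_df["value"]
    ]
    removed = TraitRecords(records.trait_name, removed_df.reset_index(drop=True))
    return retained, removed


def describe(records: TraitRecords | list[TraitRecords]) -> pd.DataFrame:
    """Descriptive statistics table: n, mean, SE, SD, CV%.

    SD uses the n-1 denominator, SE = SD/sqrt(n), CV% = 100*SD/mean
    (reported missing when the mean is 0).  Traits with a single record are
    flagged rather than summarized.
    """
    recs = [records] if isinstance(records, TraitRecords) else list(records)
    rows = []
    for r in recs:
        v = r.values
        if len(v) < 2:
            rows.append({"trait": r.trait_name, "n": len(v), "mean": np.nan,
                         "se": np.nan, "sd": np.nan, "cv_pct": np.nan,
                         "flag": "too few records"})
            continue
        mean = v.mean()
        sd = v.std(ddof=1)
        cv = 100.0 * sd / mean if mean != 0 else np.nan
        rows.append({"trait": r.trait_name, "n": len(v), "mean": mean,
                     "se": sd / np.sqrt(len(v)), "sd": sd, "cv_pct": cv,
                     "flag": "" if mean != 0 else "mean zero, CV undefined"})
    return pd.DataFrame(rows).set_index("trait")


def load_phenotypes(path, ped=None, traits: list[str] | None = None) -> dict[str, TraitRecords]:
    """Read a phenotype CSV ``animal,generation,hatch,<trait1>,...``.

    Empty cells are missing observations and become absent rows.  When a
    pedigree is supplied, animal labels are mapped to renumbered ids and the
    dam of each animal is looked up from it; otherwise dam is 0.
    """
    df = pd.read_csv(path, dtype={"animal": str})
    needed = {"animal", "generation", "hatch"}
    if not needed.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(needed)}")
    trait_cols = [c for c in df.columns if c not in needed]
    if traits is not None:
        unknown = set(traits) - set(trait_cols)
        if unknown:
            raise ValueError(f"traits not in phenotype header: {sorted(unknown)}")
        trait_cols = list(traits)
    if ped is not None:
        lmap = {str(k): v for k, v in ped.label_map().items()}
        try:
            animal = df["animal"].map(lambda a: lmap[str(a)]).to_numpy()
        except KeyError as e:
            raise ValueError(f"animal {e.args[0]!r} not in pedigree") from None
        dam = ped.dam[animal - 1]
    else:
        animal = pd.to_numeric(df["animal"]).to_numpy()
        dam = np.zeros(len(df), dtype=int)
    out = {}
    for t in trait_cols:
        vals = pd.to_numeric(df[t], errors="coerce")
        mask = vals.notna().to_numpy()
        data = pd.DataFrame({
            "animal": animal[mask],
            "dam": np.asarray(dam)[mask],
            "generation": df["generation"].to_numpy()[mask],
            "hatch": df["hatch"].to_numpy()[mask],
            "value": vals.to_numpy(dtype=float)[mask],
        })
        out[t] = TraitRecords(t, data)
    return out
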