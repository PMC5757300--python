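"""Derived host variables for the regression and niche analyses.

Builds the predictors used downstream from raw trait columns: Shannon diet
diversity over a 10-category diet composition, composite binary habitat
indicators (anthropogenic / forest / dry bush) from IUCN-style habitat
flags, centring and scaling of continuous predictors, and in-support
random imputation of missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TraitTable, ValidationError

logger = logging.getLogger("hostspec")

__all__ = [
    "shannon_diet_diversity",
    "HABITAT_COMPOSITES",
    "derive_habitat_indicators",
    "centre_and_scale",
    "impute_missing_traits",
    "PreparedTraits",
    "prepare_traits",
]


def shannon_diet_diversity(proportions: Sequence[float]) -> float:
    """Shannon index (nats) of a diet composition, -sum p ln p with
    0 ln 0 := 0; bounded by ln(n_categories)."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValidationError("diet proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError(f"diet proportions sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


#: Composite habitat indicators -> IUCN-style member flags (logical OR).
HABITAT_COMPOSITES = {
    "anthropogenic_use": ("introduced_vegetation", "artificial_terrestrial"),
    "forest_use": ("forest", "shrubland"),
    "dry_bush_use": ("desert", "savanna", "grassland"),
}


def derive_habitat_indicators(raw_habitats: Mapping[str, float]) -> tuple[int, int, int]:
    """(anthropogenic, forest, dry_bush) composites from raw habitat flags.

    Each composite is the logical OR of its member flags; missing flags count
    as absence.
    """
    out = []
    for members in HABITAT_COMPOSITES.values():
        vals = [raw_habitats.get(m) for m in members]
        vals = [0 if v is None or (isinstance(v, float) and np.isnan(v)) else v for v in vals]
        if any(v not in (0, 1, 0.0, 1.0) for v in vals):
            raise ValidationError(f"habitat flags must be 0/1/missing, got {vals}")
        out.append(int(any(v == 1 for v in vals)))
    return tuple(out)


def centre_and_scale(column: Sequence[float], name: str = "column"):
    """Centre a continuous vector and divide by one (population) SD.

    Missing entries are left missing. Returns ``(scaled, mean, sd)``; the
    recorded pair supports exact back-transformation.
    """
    x = np.asarray(column, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValidationError(f"{name}: need >= 2 observed values to scale")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=0))
    if sd == 0:
        raise ValidationError(f"{name}: zero variance, cannot scale")
    return (x - mean) / sd, mean, sd


def impute_missing_traits(table: TraitTable, seed: int) -> TraitTable:
    """Fill missing cells by uniform draws from each column's observed values.

    Fuzzy groups are imputed jointly: a row with any missing proportion gets
    a complete observed row drawn for the whole group, so compositions keep
    summing to 1. Deterministic given ``seed``; observed cells are untouched.
    """
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    grouped = {c for cols in table.fuzzy_groups.values() for c in cols}

    for group, cols in sorted(table.fuzzy_groups.items()):
        block = df[list(cols)]
        complete = block.notna().all(axis=1)
        if not complete.any():
            raise ValidationError(f"fuzzy group {group!r} has no complete row")
        donors = block[complete].to_numpy()
        needs = block.index[~complete]
        for sp in needs:
            df.loc[sp, list(cols)] = donors[rng.integers(donors.shape[0])]

    for col in df.columns:
        if col in grouped:
            continue
        vals = df[col]
        missing = vals.isna()
        if not missing.any():
            continue
        observed = vals[~missing].to_numpy()
        if observed.size == 0:
            raise ValidationError(f"column {col!r} is fully missing")
        df.loc[missing, col] = rng.choice(observed, size=int(missing.sum()))

    return TraitTable(df, dict(table.types), dict(table.fuzzy_groups))


# ---------------------------------------------------------------------------
# Prepared predictor set
# ---------------------------------------------------------------------------

#: Continuous predictors that get a centred/scaled copy (suffix ``_s``).
CONTINUOUS_PREDICTORS = (
    "body_mass_kg",
    "diet_diversity",
    "cohabitation_diversity",
    "citations_parasite",
    "citations_ectoparasite",
)


@dataclass
class PreparedTraits:
    """Regression-ready per-species variables plus the scaling record.

    ``frame`` holds the derived columns (diet_diversity, the three composite
    habitat indicators, raw and ``_s``-suffixed scaled continuous
    predictors); ``scaling`` maps each scaled column to its (mean, sd).
    """

    frame: pd.DataFrame
    scaling: dict = field(default_factory=dict)

    @property
    def species(self) -> list:
        return list(self.frame.index)

    def inverse_scale(self, column: str, scaled_values):
        mean, sd = self.scaling[column]
        return np.asarray(scaled_values, dtype=float) * sd + mean


def prepare_traits(
    table: TraitTable,
    diet_group: str = "diet",
    scale_columns: Sequence[str] = CONTINUOUS_PREDICTORS,
) -> PreparedTraits:
    """Derive diet diversity, composite habitat indicators and scaled copies
    of the continuous predictors from a complete (imputed) trait table."""
    df = table.data.copy()
    if df.isna().any().any():
        missing = sorted(df.columns[df.isna().any()])
        raise ValidationError(
            f"prepare_traits requires a complete table; impute first "
            f"(missing in {missing})"
        )
    out = pd.DataFrame(index=df.index)

    if diet_group in table.fuzzy_groups:
        cols = table.fuzzy_groups[diet_group]
        out["diet_diversity"] = [
            shannon_diet_diversity(row) for row in df[list(cols)].to_numpy()
        ]
    elif "diet_diversity" in df.columns:
        out["diet_diversity"] = df["diet_diversity"]

    flag_cols = [c for c in df.columns if table.types.get(c) == "binary"]
    composites = {name: [] for name in HABITAT_COMPOSITES}
    for _, row in df[flag_cols].iterrows():
        anth, forest, dry = derive_habitat_indicators(row.to_dict())
        composites["anthropogenic_use"].append(anth)
        composites["forest_use"].append(forest)
        composites["dry_bush_use"].append(dry)
    for name, vals in composites.items():
        out[name] = vals

    passthrough = [
        c
        for c in df.columns
        if table.types.get(c) in ("continuous", "categorical") and c not in out
    ]
    for c in passthrough:
        out[c] = df[c]

    scaling = {}
    for col in scale_columns:
        if col not in out.columns:
            continue
        scaled, mean, sd = centre_and_scale(out[col].to_numpy(dtype=float), name=col)
        out[col + "_s"] = scaled
        scaling[col] = (mean, sd)

    return PreparedTraits(out, scaling)


def write_scaling_record(prepared: PreparedTraits, path) -> None:
    """Serialise the per-column (mean, sd) pairs as ``key=mean,sd`` lines."""
    lines = [
        f"{col}={mean!r},{sd!r}" for col, (mean, sd) in sorted(prepared.scaling.items())
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
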