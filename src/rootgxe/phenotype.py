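"""Phenotype handling: least-squares genotype means, % deep roots, stress indices.

The genotype x environment cell values used everywhere downstream are
least-squares (adjusted) genotype means from the additive two-way model

    value = mu + genotype_i + block_j

fitted per environment.  With balanced complete blocks these coincide with
arithmetic genotype means (and with the mixed-model LS means of the classical
field-trial analysis); with missing plots they are the normal-equation
solutions averaged over the environment's block levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: trait key -> (index column name, kind); "reduction" = (c-s)/c*100,
#: "increase" = (s-c)/c*100, "difference" = s-c (percentage points)
STRESS_INDEX_DEFS: dict[str, tuple[str, str]] = {
    "shoot_biomass": ("pct_shoot_biomass_reduction", "reduction"),
    "rdw": ("pct_rdw_reduction", "reduction"),
    "mrl": ("pct_mrl_increase", "increase"),
    "pct_deep_roots": ("deep_root_increase_points", "difference"),
    "grain_yield": ("pct_yield_reduction", "reduction"),
}


def validate_observations(obs: pd.DataFrame) -> None:
    req = {"genotype", "environment", "block", "trait", "value"}
    missing = req - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns {sorted(missing)}")
    dup = obs.duplicated(subset=["genotype", "environment", "block", "trait"])
    if dup.any():
        first = obs.loc[dup.idxmax()]
        raise ValueError(
            "duplicate observation key "
            f"({first['genotype']}, {first['environment']}, "
            f"{first['block']}, {first['trait']})"
        )
    vals = obs["value"].to_numpy(dtype=float)
    if not np.isfinite(vals[~np.isnan(vals)]).all():
        raise ValueError("observation values must be finite where present")


def ls_means(obs: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Least-squares genotype means per environment for one trait.

    Returns a genotypes x environments DataFrame with NaN for genotypes
    absent from an environment.  Environments with fewer than two distinct
    genotypes are dropped with a logged warning.
    """
    validate_observations(obs)
    sub = obs[obs["trait"] == trait].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")

    genotypes = sorted(sub["genotype"].unique())
    columns: dict[str, pd.Series] = {}
    for env, grp in sub.groupby("environment", sort=True):
        genos = sorted(grp["genotype"].unique())
        if len(genos) < 2:
            logger.warning("environment %s has <2 genotypes; column dropped", env)
            continue
        columns[env] = _env_ls_means(grp, genos)

    if not columns:
        raise ValueError(f"no usable environments for trait {trait!r}")
    mat = pd.DataFrame(index=genotypes, columns=sorted(columns), dtype=float)
    for env, means in columns.items():
        mat.loc[means.index, env] = means
    mat.index.name = "genotype"
    mat.attrs["trait"] = trait
    return mat


def _env_ls_means(grp: pd.DataFrame, genos: list[str]) -> pd.Series:
    blocks = sorted(grp["block"].unique())
    if len(blocks) == 1:
        return grp.groupby("genotype")["value"].mean().loc[genos]
    g_idx = {g: i for i, g in enumerate(genos)}
    b_idx = {b: i for i, b in enumerate(blocks)}
    n, ng, nb = len(grp), len(genos), len(blocks)
    X = np.zeros((n, 1 + ng + nb))
    X[:, 0] = 1.0
    rows = np.arange(n)
    X[rows, 1 + grp["genotype"].map(g_idx).to_numpy()] = 1.0
    X[rows, 1 + ng + grp["block"].map(b_idx).to_numpy()] = 1.0
    beta, *_ = np.linalg.lstsq(X, grp["value"].to_numpy(dtype=float), rcond=None)
    # adjusted mean: prediction for genotype g averaged over all block levels
    means = beta[0] + beta[1:1 + ng] + beta[1 + ng:].mean()
    return pd.Series(means, index=genos)


@dataclass(frozen=True)
class DepthProfile:
    """Root dry weight by depth bin for one genotype in one environment."""

    genotype: str
    environment: str
    boundaries_cm: tuple  # strictly increasing, starting at 0
    weights_g: tuple      # one per bin, len(boundaries) - 1

    def __post_init__(self):
        b = np.asarray(self.boundaries_cm, dtype=float)
        w = np.asarray(self.weights_g, dtype=float)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("depth bin boundaries must increase strictly from 0")
        if len(w) != len(b) - 1:
            raise ValueError("need one weight per depth bin")
        if np.any(w < 0):
            raise ValueError("root weights must be non-negative")


def percent_deep_roots(profile: DepthProfile, cutoff_cm: float) -> float:
    """100 x (root mass below ``cutoff_cm``) / (total root mass).

    The cutoff must coincide with a bin boundary (no interpolation); the
    classical choices are 20 cm or 30 cm depending on the study system.
    """
    b = np.asarray(profile.boundaries_cm, dtype=float)
    w = np.asarray(profile.weights_g, dtype=float)
    if not np.any(np.isclose(b, cutoff_cm)):
        raise ValueError(f"cutoff {cutoff_cm} cm is not a bin boundary")
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"total root weight is zero for {profile.genotype}/{profile.environment}"
        )
    deep = w[b[:-1] >= cutoff_cm - 1e-12].sum()
    return float(100.0 * deep / total)


def stress_indices(
    control: Mapping[str, pd.Series],
    stress: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Drought-response indices from paired control/stress genotype values.

    Parameters
    ----------
    control, stress : mapping of trait key -> Series indexed by genotype
        Recognised trait keys and the index each produces:
        ``shoot_biomass`` -> % shoot biomass reduction, ``rdw`` -> % RDW
        reduction, ``grain_yield`` -> % yield reduction (all
        ``(control - stress)/control * 100``); ``mrl`` -> % MRL increase
        (``(stress - control)/control * 100``); ``pct_deep_roots`` ->
        %DR increase as a percentage-point difference ``stress - control``.

    Genotypes lacking either member of a pair are omitted (logged); a zero
    control value makes a ratio index undefined for that genotype — reported
    as NaN and logged, never silently dropped.
    """
    out: dict[str, pd.Series] = {}
    for trait in control:
        if trait not in STRESS_INDEX_DEFS:
            raise ValueError(f"unknown stress-index trait {trait!r}")
        if trait not in stress:
            logger.warning("trait %s missing from stress set; skipped", trait)
            continue
        name, kind = STRESS_INDEX_DEFS[trait]
        c = pd.Series(control[trait]).astype(float)
        s = pd.Series(stress[trait]).astype(float)
        shared = c.dropna().index.intersection(s.dropna().index)
        dropped = set(c.index).union(s.index) - set(shared)
        if dropped:
            logger.info("trait %s: %d genotype(s) lack a control/stress pair",
                        trait, len(dropped))
        c, s = c.loc[shared], s.loc[shared]
        if kind == "difference":
            idx = s - c
        else:
            zero = c == 0
            if zero.any():
                logger.warning("trait %s: control value 0 for %s; index undefined",
                               trait, list(shared[zero]))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (c - s) / c if kind == "reduction" else (s - c) / c
            idx = 100.0 * ratio
            idx[zero] = np.nan
        out[name] = idx
    if not out:
        raise ValueError("no paired traits provided")
    table = pd.DataFrame(out)
    table.index.name = "genotype"
    return table
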