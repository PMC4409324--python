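"""Synthetic multi-environment phenotype, introgression and QTL-set generator.

Emulates the study design behind the OryzaSNP drought panel: ~20 diverse
genotypes phenotyped in ~10-25 environments (paired well-watered control /
drought-stress treatments per site) with replicate blocks, missing
genotype-by-environment cells, binary introgression indicators over 100 kb
genome windows labelled by donor group (aus / indica / japonica), and QTL
annotation sets sampled from a fixed window population.

The plot-level phenotype model is

    y_geb = mu + G_g + E_e + sum_k lambda_k a_gk c_ek + B_eb + eps_geb

with G, E centered, the interaction built from random orthonormal factors
orthogonal to the ones vector (hence exactly double-centered), and every
component rescaled so its realized sum of squares hits the requested fraction
of the total.  That makes downstream AMMI sum-of-squares partitions land on
the requested G/E/GxE/error fractions up to error leakage alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import BlockMatrix, window_id

_STREAM_PHENOTYPE = 0
_STREAM_BLOCKS = 1
_STREAM_ANNOTATIONS = 2


class ConfigError(ValueError):
    """Raised for an infeasible simulation configuration."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    ``variance_fractions`` partitions the total plot-level variance among
    genotype main effect, environment main effect, multiplicative G×E
    interaction and residual error; the default keeps the G:E:G×E ratio of a
    multi-environment yield trial dominated by environment (roughly
    11:59:30 among the systematic components) and adds a 10% plot error
    share.  ``block_sd`` (in units of the total phenotype SD) controls random
    replicate-block effects, which least-squares means absorb.
    """

    n_genotypes: int = 20
    n_environments: int = 19
    variance_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"G": 0.10, "E": 0.53, "GxE": 0.27, "error": 0.10}
    )
    interaction_rank: int = 4
    interaction_decay: float = 0.7
    missing_rate: float = 0.05
    n_chromosomes: int = 12
    windows_per_chromosome: int = 25
    donor_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"aus": 0.05, "indica": 0.20, "japonica": 0.50}
    )
    carrier_prob: float = 0.25
    causal_windows: Sequence[tuple[int, float]] = ()
    n_blocks_per_env: int = 3
    block_sd: float = 0.25
    trait: str = "grain_yield"
    grand_mean: float = 2500.0
    total_sd: float = 800.0
    exclude_genotypes: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self):
        self.causal_windows = tuple(tuple(cw) for cw in self.causal_windows)
        self.exclude_genotypes = tuple(self.exclude_genotypes)
        self.validate()

    def validate(self) -> None:
        vf = dict(self.variance_fractions)
        missing = {"G", "E", "GxE", "error"} - vf.keys()
        if missing:
            raise ConfigError(f"variance_fractions missing keys: {sorted(missing)}")
        total = sum(vf.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"variance_fractions sum to {total}, not 1")
        if any(v < 0 for v in vf.values()):
            raise ConfigError("variance fractions must be non-negative")
        if self.n_genotypes < 3:
            raise ConfigError("need at least 3 genotypes")
        if self.n_environments < 2:
            raise ConfigError("need at least 2 environments")
        max_rank = min(self.n_genotypes, self.n_environments) - 1
        if self.interaction_rank > max_rank:
            raise ConfigError(
                f"interaction_rank {self.interaction_rank} exceeds "
                f"min(n_genotypes, n_environments) - 1 = {max_rank}"
            )
        if self.interaction_rank < 0:
            raise ConfigError("interaction_rank must be >= 0")
        if vf["GxE"] > 0 and self.interaction_rank == 0:
            raise ConfigError("GxE fraction > 0 requires interaction_rank >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_blocks_per_env < 1:
            raise ConfigError("need at least 1 block per environment")
        n_windows = self.n_chromosomes * self.windows_per_chromosome
        for widx, _ in self.causal_windows:
            if not 0 <= widx < n_windows:
                raise ConfigError(f"causal window index {widx} out of range")

    def donor_fraction_map(self) -> dict[str, float]:
        df = self.donor_fraction
        if isinstance(df, (int, float)):
            df = {g: float(df) for g in ("aus", "indica", "japonica")}
        df = dict(df)
        if sum(df.values()) > 1.0 + 1e-12:
            raise ConfigError("donor fractions sum to more than 1")
        return df

    def genotype_ids(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_genotypes)]

    def environment_ids(self) -> list[str]:
        # paired sites: control (C) / drought-stress (S) per site
        ids = []
        for e in range(self.n_environments):
            site, trt = divmod(e, 2)
            ids.append(f"s{site + 1:02d}{'C' if trt == 0 else 'S'}")
        return ids

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variance_fractions"] = dict(self.variance_fractions)
        if not isinstance(self.donor_fraction, (int, float)):
            d["donor_fraction"] = dict(self.donor_fraction)
        d["causal_windows"] = [list(cw) for cw in self.causal_windows]
        d["exclude_genotypes"] = list(self.exclude_genotypes)
        return d


@dataclass
class SyntheticTruth:
    """Ground-truth components behind one synthetic phenotype table."""

    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    interaction: pd.DataFrame
    causal_effects: dict[str, float]
    realized_variance_fractions: dict[str, float]


def _orthonormal_centered(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Random n x rank orthonormal columns orthogonal to the ones vector."""
    A = rng.standard_normal((n, rank))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q[:, :rank]


def _scale_to_ss(v: np.ndarray, target_ss: float) -> np.ndarray:
    ss = float((v ** 2).sum())
    if target_ss == 0:
        return np.zeros_like(v)
    if ss == 0:
        raise ConfigError("degenerate zero draw cannot be scaled")
    return v * np.sqrt(target_ss / ss)


def gen_phenotype(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate plot-level observations and the truth behind them.

    Returns
    -------
    obs : pandas.DataFrame
        Columns ``genotype, environment, block, trait, value``; one row per
        surviving plot.  Cells (genotype x environment) are removed completely
        at random at ``missing_rate`` (all blocks at once, mirroring a
        genotype absent from an experiment), never leaving fewer than two
        genotypes per environment or two environments per genotype.
    truth : SyntheticTruth
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_PHENOTYPE)
    ng, ne, nb = config.n_genotypes, config.n_environments, config.n_blocks_per_env
    vf = dict(config.variance_fractions)
    V = config.total_sd ** 2
    T = ng * ne * V  # total SS over the genotype x environment cell grid

    genos = config.genotype_ids()
    envs = config.environment_ids()

    g = rng.standard_normal(ng)
    g -= g.mean()
    g = _scale_to_ss(g, vf["G"] * T / ne)

    e = rng.standard_normal(ne)
    e -= e.mean()
    e = _scale_to_ss(e, vf["E"] * T / ng)

    if config.interaction_rank > 0 and vf["GxE"] > 0:
        alpha = _orthonormal_centered(rng, ng, config.interaction_rank)
        gamma = _orthonormal_centered(rng, ne, config.interaction_rank)
        lam = config.interaction_decay ** np.arange(config.interaction_rank)
        lam = lam * np.sqrt(vf["GxE"] * T / (lam ** 2).sum())
        inter = (alpha * lam) @ gamma.T
    else:
        inter = np.zeros((ng, ne))

    # causal introgression effects load on the genotype axis
    causal_effects: dict[str, float] = {}
    g_eff = g.copy()
    if config.causal_windows:
        blocks = gen_blocks(config)
        for widx, beta in config.causal_windows:
            wid = blocks.windows.index[widx]
            z = blocks.indicators[wid].reindex(genos).to_numpy(dtype=float)
            g_eff = g_eff + beta * config.total_sd * (z - z.mean())
            causal_effects[wid] = float(beta)

    blocks_eff = rng.normal(0.0, config.block_sd * config.total_sd, size=(ne, nb))
    eps = rng.standard_normal((ng, ne, nb))
    eps -= eps.mean()
    eps = _scale_to_ss(eps, vf["error"] * nb * T)

    cells = (
        config.grand_mean
        + g_eff[:, None]
        + e[None, :]
        + inter
    )
    values = cells[:, :, None] + blocks_eff[None, :, :] + eps

    # completely-at-random cell deletion, guarded so rows/columns stay usable
    keep = rng.random((ng, ne)) >= config.missing_rate
    for j in range(ne):
        if keep[:, j].sum() < 2:
            keep[np.argsort(~keep[:, j])[:2], j] = True
    for i in range(ng):
        if keep[i, :].sum() < 2:
            keep[i, np.argsort(~keep[i, :])[:2]] = True

    excluded = set(config.exclude_genotypes)
    rows = []
    for i, gid in enumerate(genos):
        if gid in excluded:
            continue
        for j, eid in enumerate(envs):
            if not keep[i, j]:
                continue
            for b in range(nb):
                rows.append((gid, eid, f"b{b + 1}", config.trait,
                             values[i, j, b]))
    obs = pd.DataFrame(rows, columns=["genotype", "environment", "block",
                                      "trait", "value"])

    ss = {
        "G": ne * nb * float(((g_eff - g_eff.mean()) ** 2).sum()),
        "E": ng * nb * float((e ** 2).sum()),
        "GxE": nb * float((inter ** 2).sum()),
        "error": float((eps ** 2).sum()),
    }
    tot = sum(ss.values())
    realized = {k: v / tot for k, v in ss.items()}

    truth = SyntheticTruth(
        grand_mean=config.grand_mean,
        genotype_effects=pd.Series(g_eff - g_eff.mean(), index=genos),
        environment_effects=pd.Series(e, index=envs),
        interaction=pd.DataFrame(inter, index=genos, columns=envs),
        causal_effects=causal_effects,
        realized_variance_fractions=realized,
    )
    return obs, truth


def gen_blocks(config: SimulationConfig) -> BlockMatrix:
    """Generate a binary genotype x window introgression matrix.

    Windows are contiguous 0-based half-open 100 kb intervals per chromosome.
    Each window is assigned at most one donor group according to
    ``donor_fraction``; carriers are drawn i.i.d. Bernoulli(``carrier_prob``)
    among genotypes, and windows with no donor group stay all-zero.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_BLOCKS)
    genos = config.genotype_ids()
    fracs = config.donor_fraction_map()

    recs = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for w in range(config.windows_per_chromosome):
            start = w * 100_000
            recs.append((chrom, start, start + 100_000))
    windows = pd.DataFrame(recs, columns=["chrom", "start", "end"])

    u = rng.random(len(windows))
    labels = np.full(len(windows), "none", dtype=object)
    lo = 0.0
    for group in ("aus", "indica", "japonica"):
        f = fracs.get(group, 0.0)
        labels[(u >= lo) & (u < lo + f)] = group
        lo += f
    # a causal window is by definition an introgression window: guarantee a
    # donor label so carriers exist for the embedded effect
    for widx, _ in config.causal_windows:
        if labels[widx] == "none":
            labels[widx] = "japonica"
    windows["donor_group"] = labels
    windows.index = [window_id(c, s, e) for c, s, e in
                     zip(windows["chrom"], windows["start"], windows["end"])]

    carriers = (rng.random((len(genos), len(windows))) <
                config.carrier_prob).astype(np.int8)
    carriers[:, labels == "none"] = 0
    indicators = pd.DataFrame(carriers, index=genos, columns=windows.index)
    return BlockMatrix(windows=windows, indicators=indicators)


def gen_qtl_annotations(
    per_qtl_window_counts: Sequence[int],
    pop_total: int = 3680,
    seed: int = 0,
    universe: Sequence[str] | None = None,
    traits: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
):
    """Sample QTL annotation window sets from a fixed population.

    Each annotation receives exactly the requested number of windows, sampled
    without replacement from ``universe`` (defaults to synthetic ids
    ``w0001..w<pop_total>``).
    """
    from .enrich import QTLAnnotation

    if universe is None:
        universe = [f"w{i + 1:04d}" for i in range(pop_total)]
    universe = list(universe)
    if len(universe) != pop_total:
        raise ConfigError(
            f"universe size {len(universe)} != pop_total {pop_total}"
        )
    rng = _rng(seed, _STREAM_ANNOTATIONS)
    annotations = []
    for q, count in enumerate(per_qtl_window_counts):
        if not 0 < count <= pop_total:
            raise ConfigError(
                f"per-QTL window count {count} infeasible for population "
                f"of {pop_total}"
            )
        chosen = rng.choice(len(universe), size=count, replace=False)
        annotations.append(QTLAnnotation(
            qtl_id=f"SQTL{q + 1:03d}",
            category=(categories[q] if categories else "synthetic"),
            trait=(traits[q] if traits else "root trait"),
            windows=frozenset(universe[i] for i in chosen),
            reference="synthetic",
        ))
    return annotations
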