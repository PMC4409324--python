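"""Introgression-block association scan and hot-spot co-location.

Each 100 kb genome window carries a binary indicator per genotype (1 = the
genotype's SNP haplotype in that window matches a donor group's representative
pattern, i.e. an introgression).  Windows are tested one at a time against a
phenotype column by simple linear regression on the 0/1 indicator; for a
binary regressor the one-way ANOVA F (1 numerator df) equals the squared
pooled-variance two-sample t, so both published formulations coincide.

Significant windows (strict p < alpha, default 0.001) are merged into maximal
book-ended regions per (donor group, trait, experiment) track, and genomic
hot spots are maximal runs of windows covered by at least ``min_traits``
distinct (trait, experiment) combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

WINDOW_SIZE = 100_000

DONOR_GROUPS = ("aus", "indica", "japonica")


def window_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class BlockMatrix:
    """Binary introgression indicators over 100 kb genome windows.

    Attributes
    ----------
    windows : pandas.DataFrame
        One row per window, columns ``chrom``, ``start``, ``end``,
        ``donor_group``; index is the window id ``chrom:start-end``.
        Coordinates are 0-based half-open and every window is exactly 100 kb.
    indicators : pandas.DataFrame
        genotypes x windows 0/1 matrix; columns align with ``windows.index``.
    """

    windows: pd.DataFrame
    indicators: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        req = {"chrom", "start", "end", "donor_group"}
        if not req.issubset(self.windows.columns):
            raise ValueError(f"windows table must have columns {sorted(req)}")
        lengths = self.windows["end"] - self.windows["start"]
        bad = self.windows.index[lengths != WINDOW_SIZE]
        if len(bad):
            raise ValueError(f"non-100kb window(s): {list(bad[:5])}")
        if not self.windows.index.equals(pd.Index(self.indicators.columns)):
            raise ValueError("indicator columns do not match window ids")
        order = self.windows.sort_values(["chrom", "start"]).index
        if not order.equals(self.windows.index):
            raise ValueError("windows must be sorted by (chromosome, start)")
        for (chrom, donor), grp in self.windows.groupby(["chrom", "donor_group"]):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(
                    f"overlapping windows on {chrom} for donor group {donor}"
                )
        vals = self.indicators.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("indicators must be 0/1")

    @property
    def genotypes(self) -> list[str]:
        return list(self.indicators.index)

    def minor_class_counts(self) -> pd.Series:
        ones = self.indicators.sum(axis=0)
        n = len(self.indicators)
        return pd.concat([ones, n - ones], axis=1).min(axis=1)


@dataclass(frozen=True)
class AssociationRecord:
    """Per-window linear-regression / one-way ANOVA test result."""

    window: str
    chrom: str
    start: int
    end: int
    donor_group: str
    trait: str
    experiment: str
    sign: int
    F: float
    p: float
    n: int
    minor_count: int


@dataclass(frozen=True)
class Region:
    """Maximal run of book-ended significant windows on one track."""

    chrom: str
    start: int
    end: int
    donor_group: str
    trait: str
    experiment: str
    windows: tuple = ()

    @property
    def track(self) -> tuple:
        return (self.trait, self.experiment)


@dataclass(frozen=True)
class Hotspot:
    """Genomic interval where >= min_traits (trait, experiment) tracks align."""

    chrom: str
    start: int
    end: int
    windows: tuple
    combinations: frozenset
    depths: tuple = ()

    @property
    def count(self) -> int:
        return len(self.combinations)


class BlockAssociationScan(BaseEstimator):
    """Window-by-window association of introgression indicators with a phenotype.

    Fit on a :class:`BlockMatrix` and a phenotype Series (one experiment's
    genotype means).  For each window with minor-class count >=
    ``min_minor_count`` the one-way ANOVA F on the binary split and its
    p-value (F distribution, 1 and n-2 df) are recorded.

    Parameters
    ----------
    min_minor_count : int, default 2
        Windows whose rarer indicator class among phenotyped genotypes is
        smaller than this are skipped (and counted in ``n_skipped_``).

    Attributes
    ----------
    records_ : list of AssociationRecord
    n_skipped_ : int
        Windows skipped for monomorphism / minor-class count.
    """

    def __init__(self, min_minor_count: int = 2):
        self.min_minor_count = min_minor_count

    def fit(self, blocks: BlockMatrix, phenotype: pd.Series,
            trait: str = "", experiment: str = ""):
        y = pd.Series(phenotype).astype(float).dropna()
        shared = [g for g in blocks.genotypes if g in y.index]
        if len(shared) < 3:
            raise ValueError(
                f"fewer than 3 genotypes shared between blocks and phenotype "
                f"({len(shared)}); experiment {experiment!r}"
            )
        if y.empty:
            raise ValueError("phenotype column is entirely missing")
        yv = y.loc[shared].to_numpy()
        Z = blocks.indicators.loc[shared].to_numpy(dtype=float)
        n = len(yv)

        n1 = Z.sum(axis=0)
        minor = np.minimum(n1, n - n1).astype(int)
        keep = minor >= self.min_minor_count
        self.n_skipped_ = int((~keep).sum())
        if self.n_skipped_:
            logger.info("skipped %d window(s) with minor-class count < %d",
                        self.n_skipped_, self.min_minor_count)

        ybar = yv.mean()
        sst = float(((yv - ybar) ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            m1 = Z.T @ yv / np.where(n1 > 0, n1, 1)
            m0 = (yv.sum() - Z.T @ yv) / np.where(n - n1 > 0, n - n1, 1)
            ssb = n1 * (n - n1) / n * (m1 - m0) ** 2
            ssw = np.maximum(sst - ssb, 0.0)
            F = np.where(ssb <= 0, 0.0,
                         np.where(ssw > 0, ssb / (ssw / (n - 2)), np.inf))
        pvals = stats.f.sf(F, 1, n - 2)
        pvals = np.where(F == 0, 1.0, pvals)
        sign = np.sign(m1 - m0).astype(int)

        records = []
        win = blocks.windows
        for j in np.flatnonzero(keep):
            wid = win.index[j]
            records.append(AssociationRecord(
                window=wid,
                chrom=win.iat[j, win.columns.get_loc("chrom")],
                start=int(win.iat[j, win.columns.get_loc("start")]),
                end=int(win.iat[j, win.columns.get_loc("end")]),
                donor_group=win.iat[j, win.columns.get_loc("donor_group")],
                trait=trait,
                experiment=experiment,
                sign=int(sign[j]),
                F=float(F[j]),
                p=float(pvals[j]),
                n=n,
                minor_count=int(minor[j]),
            ))
        self.records_ = records
        return self


def block_association(
    blocks: BlockMatrix,
    phenotype: pd.Series,
    trait: str = "",
    experiment: str = "",
    min_minor_count: int = 2,
) -> list[AssociationRecord]:
    """Functional wrapper over :class:`BlockAssociationScan`."""
    scan = BlockAssociationScan(min_minor_count=min_minor_count)
    scan.fit(blocks, phenotype, trait=trait, experiment=experiment)
    return scan.records_


def filter_significant(
    records: Iterable[AssociationRecord], alpha: float = 0.001
) -> list[AssociationRecord]:
    """Keep records with strictly p < alpha (the published cutoff is 0.001)."""
    records = list(records)
    kept = [r for r in records if r.p < alpha]
    logger.info("%d of %d association records pass p < %g",
                len(kept), len(records), alpha)
    return kept


def merge_regions(records: Iterable[AssociationRecord]) -> list[Region]:
    """Merge book-ended significant windows into maximal regions per track.

    Windows merge only when the gap between them is zero (end == next start),
    separately for each (donor group, trait, experiment, chromosome).
    """
    keyed: dict[tuple, list[AssociationRecord]] = {}
    for r in records:
        keyed.setdefault((r.donor_group, r.trait, r.experiment, r.chrom), []).append(r)
    regions: list[Region] = []
    for (donor, trait, exp, chrom), recs in sorted(keyed.items()):
        recs.sort(key=lambda r: r.start)
        run = [recs[0]]
        for r in recs[1:]:
            if r.start == run[-1].end:
                run.append(r)
            else:
                regions.append(_make_region(run, donor, trait, exp, chrom))
                run = [r]
        regions.append(_make_region(run, donor, trait, exp, chrom))
    regions.sort(key=lambda r: (r.chrom, r.start, r.donor_group, r.trait, r.experiment))
    return regions


def _make_region(run, donor, trait, exp, chrom) -> Region:
    return Region(
        chrom=chrom,
        start=min(r.start for r in run),
        end=max(r.end for r in run),
        donor_group=donor,
        trait=trait,
        experiment=exp,
        windows=tuple(r.window for r in run),
    )


def detect_hotspots(
    regions: Sequence[Region],
    min_traits: int = 5,
    window_size: int = WINDOW_SIZE,
) -> list[Hotspot]:
    """Find maximal intervals where >= min_traits (trait, experiment) tracks align.

    The genome is rasterized onto the 100 kb window grid; the co-location
    depth of a window is the number of distinct (trait, experiment)
    combinations whose regions cover it.  Maximal runs of contiguous windows
    with depth >= ``min_traits`` become hot spots.  The result is independent
    of the order in which regions are supplied.
    """
    cover: dict[tuple[str, int], set] = {}
    for reg in regions:
        for start in range(reg.start, reg.end, window_size):
            cover.setdefault((reg.chrom, start), set()).add(reg.track)

    hotspots: list[Hotspot] = []
    by_chrom: dict[str, list[int]] = {}
    for (chrom, start) in cover:
        by_chrom.setdefault(chrom, []).append(start)
    for chrom in sorted(by_chrom):
        starts = sorted(by_chrom[chrom])
        run: list[int] = []
        for s in starts:
            depth = len(cover[(chrom, s)])
            contiguous = run and s == run[-1] + window_size
            if depth >= min_traits and (not run or contiguous):
                run.append(s)
            else:
                if run:
                    hotspots.append(_make_hotspot(chrom, run, cover, window_size))
                run = [s] if depth >= min_traits else []
        if run:
            hotspots.append(_make_hotspot(chrom, run, cover, window_size))
    hotspots.sort(key=lambda h: (h.chrom, h.start))
    return hotspots


def _make_hotspot(chrom, run, cover, window_size) -> Hotspot:
    combos: set = set()
    depths = []
    for s in run:
        combos |= cover[(chrom, s)]
        depths.append(len(cover[(chrom, s)]))
    return Hotspot(
        chrom=chrom,
        start=run[0],
        end=run[-1] + window_size,
        windows=tuple(window_id(chrom, s, s + window_size) for s in run),
        combinations=frozenset(combos),
        depths=tuple(depths),
    )


def associations_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Tabulate association records (one row per tested window)."""
    return pd.DataFrame(
        [
            {
                "window": r.window, "chrom": r.chrom, "start": r.start,
                "end": r.end, "donor_group": r.donor_group, "trait": r.trait,
                "experiment": r.experiment, "sign": r.sign, "F": r.F,
                "p": r.p, "n": r.n, "minor_count": r.minor_count,
            }
            for r in records
        ]
    )
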