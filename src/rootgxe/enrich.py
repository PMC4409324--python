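"""QTL-set enrichment by one-tailed Fisher's exact test.

A selected genomic region is a set of 100 kb windows; a published QTL is
represented by the set of windows it intersects out of a fixed population of
windows (3680 in the rice introgression-block universe this package targets).
Over-representation of the QTL's windows inside the region is scored by the
upper tail of the hypergeometric distribution,

    P(X >= list_hits),   X ~ Hypergeom(N=population_total,
                                       K=population_hits,
                                       n=list_total),

which is the one-sided (enrichment-direction) Fisher's exact test on the
implied 2x2 table.  The tail is accumulated in log space via log-gamma so
p-values down to ~1e-30 and beyond remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_upper_tail(
    list_hits: int | Sequence[int],
    list_total: int,
    population_hits: int,
    population_total: int,
) -> float | np.ndarray:
    """Upper-tail hypergeometric probability P(X >= list_hits).

    Parameters
    ----------
    list_hits : int or sequence of int
        Observed overlap count(s) between the region's windows and the QTL's
        windows. A sequence evaluates the tail at each count on the same
        2x2 margins.
    list_total : int
        Number of windows in the region (draws).
    population_hits : int
        Number of windows in the whole population carrying the annotation.
    population_total : int
        Size of the window population.

    Returns
    -------
    float or ndarray
        Tail probability in (0, 1]; ``P(X >= 0) == 1`` exactly.
    """
    k = np.atleast_1d(np.asarray(list_hits, dtype=np.int64))
    scalar = np.isscalar(list_hits) or np.ndim(list_hits) == 0
    n, K, N = int(list_total), int(population_hits), int(population_total)
    if min(n, K, N) < 0 or k.min() < 0:
        raise ValueError("counts must be non-negative")
    if n > N or K > N:
        raise ValueError(
            f"list_total ({n}) and population_hits ({K}) must not exceed "
            f"population_total ({N})"
        )
    if k.max() > min(n, K):
        raise ValueError(
            f"list_hits ({k.max()}) exceeds min(list_total={n}, "
            f"population_hits={K})"
        )

    # feasible support of X given the margins
    lo = max(0, n - (N - K))
    hi = min(n, K)
    support = np.arange(lo, hi + 1)
    log_pmf = (
        _log_comb(float(K), support.astype(float))
        + _log_comb(float(N - K), (n - support).astype(float))
        - _log_comb(float(N), float(n))
    )
    # suffix log-sum-exp: log P(X >= s) for every s in the support
    log_tail = np.logaddexp.accumulate(log_pmf[::-1])[::-1]
    p = np.ones_like(k, dtype=float)
    above = k > lo  # k <= lo covers the whole support -> exactly 1
    p[above] = np.exp(log_tail[k[above] - lo])
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


@dataclass(frozen=True)
class QTLAnnotation:
    """A published QTL mapped to the 100 kb windows it intersects."""

    qtl_id: str
    category: str
    trait: str
    windows: frozenset = field(default_factory=frozenset)
    reference: str = ""

    def __post_init__(self):
        object.__setattr__(self, "windows", frozenset(self.windows))
        if not self.windows:
            raise ValueError(f"annotation {self.qtl_id!r} has an empty window set")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One region x annotation 2x2 enrichment result (Table-style row)."""

    region_id: str
    qtl_id: str
    category: str
    trait: str
    list_hits: int
    list_total: int
    population_hits: int
    population_total: int
    p: float

    def formatted_p(self) -> str:
        """p-value in scientific notation at 3 significant figures."""
        return f"{self.p:.2E}"


def enrich_region(
    region_windows: Iterable[str],
    annotations: Sequence[QTLAnnotation],
    population_total: int,
    region_id: str = "",
    universe: Iterable[str] | None = None,
) -> list[EnrichmentRecord]:
    """Score every annotation for over-representation inside one region.

    ``list_total`` is the number of windows in the region, ``list_hits`` the
    overlap with each annotation's windows and ``population_hits`` the
    annotation's genome-wide window count.  Records are returned sorted by
    ascending p (ties broken by QTL id).
    """
    windows = getattr(region_windows, "windows", region_windows)
    region_set = frozenset(windows)
    if not region_set:
        raise ValueError("region has no windows")
    if universe is not None:
        uni = frozenset(universe)
        for ann in annotations:
            unknown = ann.windows - uni
            if unknown:
                raise ValueError(
                    f"annotation {ann.qtl_id!r} references unknown windows: "
                    f"{sorted(unknown)[:5]}"
                )
    records = []
    for ann in annotations:
        hits = len(region_set & ann.windows)
        p = hypergeom_upper_tail(hits, len(region_set), len(ann.windows),
                                 population_total)
        records.append(
            EnrichmentRecord(
                region_id=region_id or "region",
                qtl_id=ann.qtl_id,
                category=ann.category,
                trait=ann.trait,
                list_hits=hits,
                list_total=len(region_set),
                population_hits=len(ann.windows),
                population_total=int(population_total),
                p=float(p),
            )
        )
    records.sort(key=lambda r: (r.p, r.qtl_id))
    return records
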