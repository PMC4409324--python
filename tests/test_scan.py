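"""Association scan: F = t² identity, null calibration, strict filtering,
region merging and hot-spot co-location."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootgxe.scan import (AssociationRecord, BlockMatrix, Region,
                          block_association, detect_hotspots,
                          filter_significant, merge_regions)

from conftest import make_block_matrix


def _one_window(indicator):
    genos = [f"g{i:02d}" for i in range(len(indicator))]
    ind = pd.DataFrame({"w": indicator}, index=genos).T
    return make_block_matrix(ind.T), genos


def test_f_equals_squared_two_sample_t(rng):
    """Regression-on-indicator F equals the pooled-variance t squared."""
    for _ in range(50):
        n = int(rng.integers(6, 25))
        z = np.zeros(n, dtype=int)
        z[:int(rng.integers(2, n - 1))] = 1
        rng.shuffle(z)
        y = rng.normal(0, 1, n) + 0.8 * z
        blocks, genos = _one_window(z)
        rec = block_association(blocks, pd.Series(y, index=genos))[0]
        t, p = stats.ttest_ind(y[z == 1], y[z == 0], equal_var=True)
        assert rec.F == pytest.approx(t ** 2, rel=1e-10)
        assert rec.p == pytest.approx(p, rel=1e-10)
        assert rec.sign == np.sign(y[z == 1].mean() - y[z == 0].mean())


def test_two_group_example_matches_hand_t():
    blocks, genos = _one_window([1, 1, 1, 0, 0, 0])
    y = pd.Series([5.0, 6.0, 7.0, 1.0, 2.0, 3.0], index=genos)
    rec = block_association(blocks, y)[0]
    # pooled t by hand: diff 4, s_p^2 = 1, se = sqrt(1*(1/3+1/3))
    t = 4.0 / np.sqrt(2.0 / 3.0)
    assert rec.F == pytest.approx(t ** 2, rel=1e-12)
    assert rec.sign == 1


def test_constant_phenotype_gives_f_zero_p_one():
    blocks, genos = _one_window([1, 1, 0, 0, 1, 0])
    rec = block_association(blocks, pd.Series(5.0, index=genos))[0]
    assert rec.F == 0.0 and rec.p == 1.0


def test_monomorphic_and_rare_windows_skipped(rng):
    genos = [f"g{i:02d}" for i in range(10)]
    ind = pd.DataFrame({"a": [0] * 10, "b": [1] + [0] * 9,
                        "c": [1, 1] + [0] * 8}, index=genos)
    blocks = make_block_matrix(ind)
    recs = block_association(blocks, pd.Series(rng.normal(size=10), index=genos))
    assert [r.window.split(":")[1] for r in recs] == ["200000-300000"]
    assert recs[0].minor_count == 2


def test_null_p_values_are_uniform(rng):
    """No causal windows: p < 0.001 rate in binomial range; K-S uniformity."""
    n_windows, n_geno = 2000, 20
    genos = [f"g{i:02d}" for i in range(n_geno)]
    ind = pd.DataFrame(rng.integers(0, 2, (n_geno, n_windows)), index=genos)
    blocks = make_block_matrix(ind)
    y = pd.Series(rng.normal(size=n_geno), index=genos)
    pvals = np.array([r.p for r in block_association(blocks, y)])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_causal_window_power():
    """A 3-SD effect on a balanced 10/10 split is recovered at p < 0.001
    in the vast majority of replicates."""
    rng = np.random.default_rng(11)
    genos = [f"g{i:02d}" for i in range(20)]
    z = np.array([1] * 10 + [0] * 10)
    blocks = make_block_matrix(pd.DataFrame({"w": z}, index=genos))
    hits = 0
    for _ in range(200):
        y = pd.Series(rng.normal(0, 1, 20) + 3.0 * z, index=genos)
        hits += block_association(blocks, y)[0].p < 0.001
    assert hits / 200 > 0.8


def _rec(start, p, trait="rdw", exp="E1", chrom="chr01", donor="japonica"):
    return AssociationRecord(
        window=f"{chrom}:{start}-{start + 100000}", chrom=chrom, start=start,
        end=start + 100000, donor_group=donor, trait=trait, experiment=exp,
        sign=1, F=20.0, p=p, n=20, minor_count=5)


def test_filter_is_strict():
    recs = [_rec(0, 0.001), _rec(100000, 0.0005), _rec(200000, 0.002)]
    kept = filter_significant(recs, alpha=0.001)
    assert [r.start for r in kept] == [100000]
    assert len(filter_significant(recs, alpha=1.0)) == 3


def test_merge_adjacent_windows():
    regions = merge_regions([_rec(39_700_000, 1e-5), _rec(39_800_000, 1e-5)])
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (39_700_000, 39_900_000)


def test_gap_splits_regions():
    regions = merge_regions([_rec(0, 1e-5), _rec(200_000, 1e-5)])
    assert [(r.start, r.end) for r in regions] == [(0, 100_000),
                                                   (200_000, 300_000)]


def test_merge_matches_interval_oracle(rng):
    """Random significant window sets merge identically to a brute-force
    interval union."""
    for _ in range(20):
        starts = sorted(rng.choice(30, size=10, replace=False) * 100_000)
        recs = [_rec(int(s), 1e-5) for s in starts]
        regions = merge_regions(recs)
        # oracle: walk the sorted starts, split when gap > window size
        expected = []
        run = [starts[0]]
        for s in starts[1:]:
            if s == run[-1] + 100_000:
                run.append(s)
            else:
                expected.append((run[0], run[-1] + 100_000))
                run = [s]
        expected.append((run[0], run[-1] + 100_000))
        assert [(r.start, r.end) for r in regions] == expected


def _region(track, start_w, end_w, chrom="chr01"):
    trait, exp = track
    return Region(chrom=chrom, start=start_w * 100_000, end=end_w * 100_000,
                  donor_group="japonica", trait=trait, experiment=exp)


def test_hotspot_threshold_boundary():
    tracks = [("rdw", f"E{i}") for i in range(5)]
    regions = [_region(t, 3, 4) for t in tracks]
    hs = detect_hotspots(regions, min_traits=5)
    assert len(hs) == 1 and hs[0].count == 5
    assert (hs[0].start, hs[0].end) == (300_000, 400_000)
    assert detect_hotspots(regions[:4], min_traits=5) == []


def test_hotspot_spans_depth_profile():
    """Staggered tracks with co-location depths {3,5,6,5,2} across five
    consecutive windows: the hotspot is exactly the depth >= 5 run."""
    spans = {("t1", "E"): (0, 4), ("t2", "E"): (0, 4), ("t3", "E"): (0, 3),
             ("t4", "E"): (1, 5), ("t5", "E"): (1, 5), ("t6", "E"): (2, 4)}
    regions = [_region(track, a, b) for track, (a, b) in spans.items()]
    # brute-force depth per window
    depth = [sum(a <= w < b for a, b in spans.values()) for w in range(5)]
    assert depth == [3, 5, 6, 5, 2]
    hs = detect_hotspots(regions, min_traits=5)
    assert len(hs) == 1
    assert (hs[0].start, hs[0].end) == (100_000, 400_000)
    assert list(hs[0].depths) == [5, 6, 5]
    assert hs[0].count == 6  # union of aligned (trait, experiment) combos


def test_hotspots_invariant_to_region_order(rng):
    tracks = [(f"t{i}", "E") for i in range(8)]
    regions = [_region(t, int(rng.integers(0, 5)), int(rng.integers(5, 10)))
               for t in tracks]
    ref = detect_hotspots(regions, min_traits=5)
    for _ in range(5):
        shuffled = list(regions)
        rng.shuffle(shuffled)
        assert detect_hotspots(shuffled, min_traits=5) == ref


def test_block_matrix_validation():
    genos = ["g1", "g2"]
    ind = pd.DataFrame({"w": [0, 1]}, index=genos)
    windows = pd.DataFrame({"chrom": ["chr01"], "start": [0], "end": [50_000],
                            "donor_group": ["aus"]}, index=["chr01:0-50000"])
    bad = ind.copy()
    bad.columns = windows.index
    with pytest.raises(ValueError, match="100kb"):
        BlockMatrix(windows=windows, indicators=bad)
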