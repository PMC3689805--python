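import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnaimap.phenotype import strain_induced_lethality
from rnaimap.qtlmap import (
    IntervalMapping,
    ScanResult,
    genotype_probs,
    lod_support_interval,
    permutation_threshold,
    scan_normal,
    scan_np,
)
from rnaimap.simulate import (
    GeneticMap,
    GenotypePanel,
    architecture_preset,
    default_map,
    haldane,
    simulate_phenotypes,
    simulate_riail_panel,
)

LOD_SCALE = 2.0 * np.log(10.0)


def _panel(gmap, codes, names=None):
    codes = np.asarray(codes, dtype=np.int8)
    names = names or [f"L{i}" for i in range(codes.shape[0])]
    return GenotypePanel(gmap=gmap, codes=codes, line_names=names)


def brute_kruskal_wallis(y, groups):
    """Independent textbook Kruskal-Wallis H with midranks and tie
    correction (no shared code with the scan)."""
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(y)
    n = y.size
    h = 0.0
    for g in np.unique(groups):
        rg = ranks[groups == g]
        h += rg.sum() ** 2 / rg.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(y, return_counts=True)
    return h / (1.0 - (counts**3 - counts).sum() / (n**3 - n))


# ---------------------------------------------------------------------------
# genotype posteriors


def test_posterior_is_certain_at_typed_markers(small_panel):
    grid = genotype_probs(small_panel, step_cM=1.0)
    for marker in ("cI_000.0", "cI_020.0", "cII_040.0"):
        idx = small_panel.gmap.marker_index(marker)
        chrom = small_panel.gmap.table["chrom"].iloc[idx]
        pos = small_panel.gmap.table["pos_cM"].iloc[idx]
        j = np.flatnonzero((grid.chrom == chrom) & (grid.pos_cM == pos))[0]
        expected = (small_panel.codes[:, idx] == 0).astype(float)
        assert np.array_equal(grid.p_n2[:, j], expected)


def test_posterior_midpoint_concordant_and_discordant():
    gmap = GeneticMap(["m1", "m2"], ["I", "I"], [0.0, 2.0])
    panel = _panel(gmap, [[0, 0], [1, 1], [0, 1], [1, 0]])
    grid = genotype_probs(panel, step_cM=1.0)
    j = np.flatnonzero(grid.pos_cM == 1.0)[0]
    r = haldane(1.0)
    concordant = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
    assert grid.p_n2[0, j] == pytest.approx(concordant)
    assert concordant > 0.99
    assert grid.p_n2[1, j] == pytest.approx(1 - concordant)
    assert grid.p_n2[2, j] == pytest.approx(0.5)
    assert grid.p_n2[3, j] == pytest.approx(0.5)


def test_posterior_marginalizes_missing_markers():
    """A missing middle marker defers to the nearest informative flanks;
    an individual with no data at all sits at 1/2 everywhere."""
    gmap = GeneticMap(["m1", "m2", "m3"], ["I"] * 3, [0.0, 5.0, 10.0])
    panel = _panel(gmap, [[0, -1, 0], [-1, -1, -1]])
    grid = genotype_probs(panel, step_cM=1.0)
    j = np.flatnonzero(grid.pos_cM == 5.0)[0]
    r = haldane(5.0)
    expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
    assert grid.p_n2[0, j] == pytest.approx(expected)
    assert np.all(grid.p_n2[1] == 0.5)


def test_posterior_beyond_terminal_marker_single_flank():
    gmap = GeneticMap(["m1", "m2"], ["I", "I"], [2.0, 4.0])
    panel = _panel(gmap, [[1, 1]])
    grid = genotype_probs(panel, step_cM=1.0)
    assert grid.pos_cM.min() == 2.0  # grid spans typed region only
    j = np.flatnonzero(grid.pos_cM == 3.0)[0]
    assert grid.p_n2[0, j] < 0.01


# ---------------------------------------------------------------------------
# nonparametric scan


def test_scan_np_constant_phenotype_gives_zero(small_panel):
    res = scan_np(genotype_probs(small_panel), np.ones(small_panel.n_lines))
    assert (res.table["lod"] == 0.0).all()


def test_scan_np_textbook_example():
    """Groups {1,2,3} vs {4,5,6} at a fully informative marker give the
    textbook Kruskal-Wallis H = 3.857 and lod = H / (2 ln 10)."""
    gmap = GeneticMap(["m1"], ["I"], [0.0])
    panel = _panel(gmap, [[0], [0], [0], [1], [1], [1]])
    res = scan_np(genotype_probs(panel), [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    h = res.table["lod"].iloc[0] * LOD_SCALE
    assert h == pytest.approx(27 / 7, abs=1e-12)


def test_scan_np_matches_scipy_at_informative_markers():
    gmap = GeneticMap([f"m{i}" for i in range(4)], ["I"] * 4,
                      [0.0, 5.0, 10.0, 15.0])
    rng = np.random.default_rng(3)
    codes = rng.integers(0, 2, size=(12, 4))
    y = rng.normal(size=12)
    y[3] = y[5]  # force a tie to exercise the correction
    panel = _panel(gmap, codes)
    res = scan_np(genotype_probs(panel), y)
    for k, marker_pos in enumerate([0.0, 5.0, 10.0, 15.0]):
        j = np.flatnonzero(res.table["pos_cM"] == marker_pos)[0]
        g = codes[:, k]
        expected = stats.kruskal(y[g == 0], y[g == 1]).statistic
        assert res.table["lod"].iloc[j] * LOD_SCALE == pytest.approx(expected)


def test_scan_np_exhaustive_small_n_oracle():
    """Every assignment of 8 lines to two genotype groups agrees with an
    independent textbook Kruskal-Wallis implementation."""
    gmap = GeneticMap(["m1"], ["I"], [0.0])
    y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
    for combo in itertools.product([0, 1], repeat=8):
        g = np.array(combo)
        if g.min() == g.max():
            continue
        panel = _panel(gmap, g[:, None])
        res = scan_np(genotype_probs(panel), y)
        assert res.table["lod"].iloc[0] * LOD_SCALE == pytest.approx(
            brute_kruskal_wallis(y, g), abs=1e-10
        )


def test_scan_np_monotone_transform_invariance(small_panel, rng):
    y = rng.normal(size=small_panel.n_lines)
    grid = genotype_probs(small_panel)
    a = scan_np(grid, y).table["lod"]
    b = scan_np(grid, np.exp(3 * y) - 1).table["lod"]
    assert np.allclose(a, b)


def test_scan_lods_are_finite_and_nonnegative(small_panel, rng):
    grid = genotype_probs(small_panel)
    y = rng.normal(size=small_panel.n_lines)
    for res in (scan_np(grid, y), scan_normal(grid, y)):
        lod = res.table["lod"].to_numpy()
        assert np.all(np.isfinite(lod)) and np.all(lod >= 0)


# ---------------------------------------------------------------------------
# normal-model (Haley-Knott) scan


def test_scan_normal_matches_direct_least_squares(small_panel, rng):
    grid = genotype_probs(small_panel)
    y = rng.normal(size=small_panel.n_lines) + 0.8 * grid.p_n2[:, 10]
    res = scan_normal(grid, y)
    n = y.size
    for j in [0, 10, 25]:
        x_full = np.column_stack([np.ones(n), grid.p_n2[:, j]])
        rss_full = np.linalg.lstsq(x_full, y, rcond=None)[1][0]
        rss_null = np.sum((y - y.mean()) ** 2)
        expected = 0.5 * n * np.log10(rss_null / rss_full)
        assert res.table["lod"].iloc[j] == pytest.approx(expected, abs=1e-8)


def test_scan_normal_constant_covariate_equals_plain_scan(small_panel, rng):
    grid = genotype_probs(small_panel)
    y = rng.normal(size=small_panel.n_lines)
    plain = scan_normal(grid, y).table["lod"]
    with_const = scan_normal(grid, y,
                             covariate=np.full(y.size, 2.5)).table["lod"]
    assert np.allclose(plain, with_const)


def test_scan_normal_causal_covariate_absorbs_signal(small_panel, rng):
    """Conditioning on the causal dosage leaves ~no lod at that locus —
    the in-silico analog of a secondary scan recovering nothing."""
    grid = genotype_probs(small_panel)
    causal = 12
    y = 2.0 * grid.p_n2[:, causal] + 0.05 * rng.normal(
        size=small_panel.n_lines)
    plain = scan_normal(grid, y)
    conditioned = scan_normal(grid, y, covariate=grid.p_n2[:, causal])
    assert plain.table["lod"].iloc[causal] > 10
    assert conditioned.table["lod"].iloc[causal] < 0.5


def test_scan_normal_collinear_dosage_warns_and_zeroes(rng):
    gmap = GeneticMap(["m1", "m2"], ["I", "I"], [0.0, 5.0])
    codes = rng.integers(0, 2, size=(30, 1))
    panel = _panel(gmap, np.repeat(codes, 2, axis=1))
    grid = genotype_probs(panel, step_cM=5.0)
    y = rng.normal(size=30)
    with pytest.warns(UserWarning, match="collinear"):
        res = scan_normal(grid, y, covariate=codes[:, 0].astype(float))
    j = np.flatnonzero(grid.pos_cM == 0.0)[0]
    assert res.table["lod"].iloc[j] == 0.0


# ---------------------------------------------------------------------------
# permutations


def test_permutation_threshold_deterministic_and_alpha_one(small_panel, rng):
    grid = genotype_probs(small_panel)
    y = rng.normal(size=small_panel.n_lines)
    a = permutation_threshold(grid, y, n_perm=50, seed=5)
    b = permutation_threshold(grid, y, n_perm=50, seed=5)
    assert np.array_equal(a.max_lods, b.max_lods)
    assert a.threshold(alpha=1.0) == pytest.approx(a.max_lods.min())
    assert a.threshold(0.05) >= a.threshold(0.5)


def test_permutation_constant_phenotype_all_zero(small_panel):
    grid = genotype_probs(small_panel)
    res = permutation_threshold(grid, np.full(small_panel.n_lines, 0.7),
                                n_perm=25, seed=2)
    assert np.all(res.max_lods == 0.0)


def test_permutation_requires_enough_permutations(small_panel):
    grid = genotype_probs(small_panel)
    with pytest.raises(ValueError):
        permutation_threshold(grid, np.zeros(small_panel.n_lines), n_perm=5)


# ---------------------------------------------------------------------------
# support intervals


def _scan_from(lods, positions=None, chrom="I"):
    positions = positions if positions is not None else np.arange(len(lods),
                                                                  dtype=float)
    return ScanResult(
        table=pd.DataFrame({"chrom": chrom, "pos_cM": positions,
                            "lod": np.asarray(lods, dtype=float)}),
        method="np",
    )


def test_support_interval_steep_peak_three_points():
    scan = _scan_from([0.1, 0.2, 6.0, 0.2, 0.1])
    assert scan.support_interval(drop=1.5) == ("I", 1.0, 3.0)


def test_support_interval_covers_plateau():
    scan = _scan_from([0.0, 4.9, 5.0, 5.0, 5.0, 0.0])
    chrom, lo, hi = scan.support_interval(drop=1.5)
    assert (chrom, lo, hi) == ("I", 0.0, 5.0)


def test_support_interval_flat_scan_warns_whole_chromosome():
    scan = _scan_from([1.0, 1.0, 1.0, 1.0])
    with pytest.warns(UserWarning, match="flat"):
        chrom, lo, hi = scan.support_interval()
    assert (lo, hi) == (0.0, 3.0)


def test_support_interval_coverage_of_causal_locus():
    """Across seeded major-effect panels the 1.5-lod interval contains
    the causal position in at least 90% of replicates."""
    gmap = default_map(chromosomes=("I", "II"), length_cM=40.0,
                       spacing_cM=2.0)
    arch = architecture_preset("ppw1_only", background=0.05)
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        panel = simulate_riail_panel(gmap, n_lines=150, g_intercross=6,
                                     seed=1000 + rep)
        plates = simulate_phenotypes(panel, arch, seed=2000 + rep)
        pheno = strain_induced_lethality(plates)
        res = IntervalMapping(panel, pheno).fit("np")
        chrom, lo, hi = res.support_interval(drop=1.5)
        if chrom == "I" and lo <= 20.0 <= hi:
            hits += 1
    assert hits / n_rep >= 0.9


# ---------------------------------------------------------------------------
# model object


def test_interval_mapping_aligns_series_by_line_name(small_panel, rng):
    y = pd.Series(rng.normal(size=small_panel.n_lines),
                  index=small_panel.line_names)
    shuffled = y.sample(frac=1.0, random_state=0)
    a = IntervalMapping(small_panel, y).fit("np").table["lod"]
    b = IntervalMapping(small_panel, shuffled).fit("np").table["lod"]
    assert np.allclose(a, b)


def test_interval_mapping_rejects_bad_phenotype(small_panel):
    with pytest.raises(ValueError):
        IntervalMapping(small_panel, np.zeros(small_panel.n_lines - 1))
    bad = np.zeros(small_panel.n_lines)
    bad[0] = np.nan
    with pytest.raises(ValueError):
        IntervalMapping(small_panel, bad)


def test_interval_mapping_np_rejects_covariate(small_panel, rng):
    y = rng.normal(size=small_panel.n_lines)
    model = IntervalMapping(small_panel, y, covariate=y.copy())
    with pytest.raises(ValueError, match="normal"):
        model.fit("np")


def test_scan_summary_reports_peak(small_panel, rng):
    y = rng.normal(size=small_panel.n_lines)
    model = IntervalMapping(small_panel, y)
    res = model.fit("np")
    res.threshold = model.permutation_threshold(n_perm=30, seed=1).threshold()
    text = res.summary()
    assert "peak" in text and "threshold" in text
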