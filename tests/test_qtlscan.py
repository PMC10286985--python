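"""Scan engine: HMM genotype probabilities, LOD oracles, intervals, CIM."""

import math

import numpy as np
import pandas as pd
import pytest

from lunaqtl import crossmap as cm, qtlscan as qs, synthdata as sd

# --- genotype probabilities -------------------------------------------------


def _two_marker_bc(calls_by_marker, gap_cM=20.0):
    markers = cm.MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ["L", "R"],
                "chromosome": "chr1",
                "position_bp": [1, 2],
                "position_cM": [0.0, gap_cM],
            }
        )
    )
    n = len(next(iter(calls_by_marker.values())))
    calls = pd.DataFrame(calls_by_marker, index=[f"i{k}" for k in range(n)])
    return cm.GenotypeMatrix("BC", markers, calls)


def test_probability_one_at_typed_marker_no_error():
    mat = _two_marker_bc({"L": ["AA"], "R": ["AB"]})
    grid = qs.genotype_probabilities(mat, step_cM=None, error_rate=0.0)
    np.testing.assert_allclose(grid.probs[0, 0], [1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(grid.probs[0, 1], [0.0, 1.0], atol=1e-12)


def test_all_missing_individual_gets_prior():
    mat = _two_marker_bc({"L": ["-", "AA"], "R": ["-", "AA"]})
    grid = qs.genotype_probabilities(mat, step_cM=5.0)
    np.testing.assert_allclose(grid.probs[0], 0.5, atol=1e-12)
    f2 = sd.simulate_cross(sd.ArchitectureConfig(), "F2", 2, seed=1, with_emergence=False)
    calls = f2.matrix.calls.copy()
    calls.iloc[0, :] = "-"
    mat2 = cm.GenotypeMatrix("F2", f2.matrix.markers, calls)
    grid2 = qs.genotype_probabilities(mat2, step_cM=None)
    expected = np.tile([0.25, 0.5, 0.25], (grid2.n_positions, 1))
    np.testing.assert_allclose(grid2.probs[0], expected, atol=1e-10)


def test_midpoint_probability_matches_transition_matrix_product():
    """Oracle: explicit 2-state matrix computation for the midpoint of a
    20 cM gap flanked by AA/AA in a BC."""
    mat = _two_marker_bc({"L": ["AA"], "R": ["AA"]}, gap_cM=20.0)
    grid = qs.genotype_probabilities(mat, step_cM=10.0, error_rate=0.0)
    mid = grid.positions.index[grid.positions["pos_cM"] == 10.0][0]
    r = float(cm.kosambi_r(10.0))
    # P(mid=AA | both flanks AA) by Bayes over the two-step chain
    p_aa = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
    np.testing.assert_allclose(grid.probs[0, mid, 0], p_aa, atol=1e-10)


def test_probabilities_sum_to_one(bc_grid):
    np.testing.assert_allclose(bc_grid.probs.sum(axis=2), 1.0, atol=1e-9)


# --- scan_single ------------------------------------------------------------


def test_perfect_signal_peaks_at_marker(bc_grid):
    dosage = bc_grid.genetic_design()[:, :, 0]  # (P, n)
    j = 60
    scan = qs.scan_single(bc_grid, dosage[j])
    assert scan.table["lod"].idxmax() == j


def test_single_marker_lod_matches_correlation_formula(bc_grid, bc_phenotype):
    """Closed-form oracle: with a single predictor the Haley-Knott LOD is
    (n/2) log10(1 / (1 - r^2)) for the phenotype-dosage correlation r."""
    scan = qs.scan_single(bc_grid, bc_phenotype)
    G = bc_grid.genetic_design()
    n = len(bc_phenotype)
    for j in [0, 40, 80, 120]:
        r = np.corrcoef(G[j, :, 0], bc_phenotype)[0, 1]
        expected = 0.5 * n * math.log10(1.0 / (1.0 - r**2))
        assert scan.table["lod"].iloc[j] == pytest.approx(expected, abs=1e-8)


def test_lod_affine_invariance(bc_grid, bc_phenotype):
    a = qs.scan_single(bc_grid, bc_phenotype)
    b = qs.scan_single(bc_grid, 3.0 * np.asarray(bc_phenotype) - 11.0)
    np.testing.assert_allclose(a.table["lod"], b.table["lod"], atol=1e-8)


def test_degenerate_phenotype_errors(bc_grid):
    with pytest.raises(ValueError, match="degenerate"):
        qs.scan_single(bc_grid, np.ones(len(bc_grid.individuals)))


def test_binary_scan_requires_01(bc_grid):
    with pytest.raises(ValueError):
        qs.scan_single(bc_grid, np.linspace(0, 1, len(bc_grid.individuals)), model="binary")


def test_binary_scan_matches_statsmodels_logit(bc_grid, bc_sim):
    """Independent oracle: logistic LRT LOD from statsmodels at a few positions."""
    import statsmodels.api as sm

    y = bc_sim.true_insensitive.astype(float)
    scan = qs.scan_single(bc_grid, y, model="binary")
    G = bc_grid.genetic_design()
    ll0 = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    for j in [10, 60, 100]:
        X = sm.add_constant(G[j])
        ll1 = sm.Logit(y, X).fit(disp=0, method="newton").llf
        expected = max((ll1 - ll0) / math.log(10), 0.0)
        assert scan.table["lod"].iloc[j] == pytest.approx(expected, abs=1e-4)


# --- permutation threshold --------------------------------------------------


def test_threshold_deterministic_given_seed(bc_grid, bc_phenotype):
    t1 = qs.permutation_threshold(bc_grid, bc_phenotype, n_perm=100, seed=9)
    t2 = qs.permutation_threshold(bc_grid, bc_phenotype, n_perm=100, seed=9)
    assert t1 == t2


def test_threshold_alpha_one_is_minimum(bc_grid, bc_phenotype):
    tmin = qs.permutation_threshold(bc_grid, bc_phenotype, n_perm=100, alpha=1.0, seed=9)
    t05 = qs.permutation_threshold(bc_grid, bc_phenotype, n_perm=100, alpha=0.05, seed=9)
    assert tmin <= t05


def test_null_phenotype_rarely_exceeds_threshold(bc_grid):
    """Permuted (null) phenotypes stay below the 1000-permutation 5%
    threshold in >= 94% of 100 null datasets."""
    rng = np.random.default_rng(31)
    n = len(bc_grid.individuals)
    y = rng.normal(size=n)
    thr = qs.permutation_threshold(bc_grid, y, n_perm=1000, seed=17)
    exceed = 0
    for _ in range(100):
        scan = qs.scan_single(bc_grid, rng.permutation(y))
        exceed += scan.max_lod > thr
    assert exceed <= 6


# --- bayes interval ---------------------------------------------------------


def _scan_from_profile(lods):
    table = pd.DataFrame(
        {"chromosome": "chr1", "pos_cM": np.arange(len(lods), dtype=float), "lod": lods}
    )
    return qs.ScanResult(table=table, model="quantitative")


def test_interval_single_spike():
    scan = _scan_from_profile([0, 0, 9, 0, 0])
    assert qs.bayes_interval(scan, "chr1") == (2.0, 2.0)


def test_interval_flat_profile_returns_chromosome():
    scan = _scan_from_profile([1.0] * 6)
    assert qs.bayes_interval(scan, "chr1") == (0.0, 5.0)


def test_interval_matches_brute_force():
    """Oracle: enumerate all contiguous intervals containing the peak and
    take the shortest with >= 95% mass."""
    lods = np.array([0.1, 0.5, 1.2, 2.0, 1.4, 0.8, 0.2, 0.05])
    scan = _scan_from_profile(lods)
    lo, hi = qs.bayes_interval(scan, "chr1")
    dens = 10.0**lods
    dens /= dens.sum()
    peak = int(np.argmax(dens))
    best = None
    for a in range(peak + 1):
        for b in range(peak, len(lods)):
            if dens[a : b + 1].sum() >= 0.95:
                if best is None or (b - a) < (best[1] - best[0]):
                    best = (a, b)
    assert (lo, hi) == (float(best[0]), float(best[1]))
    assert lo <= peak <= hi


# --- CIM --------------------------------------------------------------------


def test_cim_zero_cofactors_reduces_to_scan_single(bc_grid, bc_phenotype):
    a = qs.cim_scan(bc_grid, bc_phenotype, n_cofactors=0)
    b = qs.scan_single(bc_grid, bc_phenotype)
    np.testing.assert_allclose(a.table["lod"], b.table["lod"], atol=1e-9)


def test_cim_excludes_cofactor_inside_window(bc_grid, bc_phenotype):
    """At the position of a cofactor the cofactor itself must leave the
    model, so the LOD there stays positive rather than collapsing to ~0."""
    scan = qs.cim_scan(bc_grid, bc_phenotype, n_cofactors=5, window_cM=10.0)
    peak_lod = scan.table["lod"].max()
    assert peak_lod > 1.0  # cofactor at the peak would squash this to ~0


def test_cim_separates_linked_qtls():
    """Two linked QTLs 40 cM apart: CIM shows two local maxima where the
    plain scan shows one broad plateau (fixed-seed fixture)."""
    arch = sd.ArchitectureConfig(
        loci=[
            sd.Locus("chr1", 30.0, mode="additive", penetrance=(0.05, 0.45, 0.9)),
            sd.Locus("chr1", 70.0, mode="additive", penetrance=(0.05, 0.45, 0.9)),
        ]
    )
    sim = sd.simulate_cross(arch, "F2", 400, seed=71, with_emergence=False)
    grid = qs.genotype_probabilities(sim.matrix, step_cM=None)
    rng = np.random.default_rng(4)
    y = sim.true_insensitive + rng.normal(0, 0.3, 400)
    cim = qs.cim_scan(grid, y, n_cofactors=5, window_cM=10.0)
    sub = cim.table[cim.table["chromosome"] == "chr1"]
    lods = sub["lod"].to_numpy()
    pos = sub["pos_cM"].to_numpy()
    near_a = lods[(pos >= 20) & (pos <= 40)].max()
    near_b = lods[(pos >= 60) & (pos <= 80)].max()
    valley = lods[(pos > 45) & (pos < 55)].min()
    assert near_a > valley and near_b > valley


# --- scan_pairs -------------------------------------------------------------


def test_lodi_identity(bc_grid, bc_phenotype):
    pairs = qs.scan_pairs(bc_grid, bc_phenotype, step_cM=20.0)
    np.testing.assert_allclose(
        pairs.lod_int, np.clip(pairs.lod_full - pairs.lod_add, 0, None), atol=1e-9
    )


def test_interaction_only_architecture_found_by_lodi():
    """Epistatic architecture with no marginal effects: the LODi peak lands
    on the true interacting pair."""
    arch = sd.ArchitectureConfig(
        loci=[sd.Locus("chr1", 50.0, mode="additive", penetrance=(0, 0, 0)),
              sd.Locus("chr3", 50.0, mode="additive", penetrance=(0, 0, 0))],
        epistatic_pairs={(0, 1): {  # XOR-like: penetrance when allele counts agree
            (a, b): (0.9 if (a > 0) == (b > 0) else 0.1) for a in range(3) for b in range(3)
        }},
    )
    sim = sd.simulate_cross(arch, "F2", 500, seed=83, with_emergence=False)
    grid = qs.genotype_probabilities(sim.matrix, step_cM=None)
    pairs = qs.scan_pairs(grid, sim.true_insensitive.astype(float), step_cM=10.0)
    (c1, p1), (c2, p2) = pairs.peak_int
    assert {c1, c2} == {"chr1", "chr3"}
    for c, p in [(c1, p1), (c2, p2)]:
        assert abs(p - 50.0) <= 20.0


# --- fit_multiple_qtl -------------------------------------------------------


def test_single_term_perfect_dosage_explains_all(bc_grid):
    dosage = bc_grid.genetic_design()[:, :, 0]
    j = 60
    chrom = bc_grid.positions.iloc[j]["chromosome"]
    cm_pos = bc_grid.positions.iloc[j]["pos_cM"]
    fit = qs.fit_multiple_qtl(bc_grid, dosage[j], [(chrom, cm_pos)])
    assert fit.pct_variance_full == pytest.approx(100.0, abs=1e-6)


def test_fit_reproduces_scan_lod_at_peak(bc_grid, bc_phenotype):
    scan = qs.scan_single(bc_grid, bc_phenotype)
    fit = qs.fit_multiple_qtl(bc_grid, bc_phenotype, [(scan.peak_chromosome, scan.peak_cM)])
    assert fit.lod_full == pytest.approx(scan.max_lod, abs=1e-6)


def test_noise_phenotype_explains_little(bc_grid):
    pcts = []
    for s in range(6):
        rng = np.random.default_rng(900 + s)
        y = rng.normal(size=len(bc_grid.individuals))
        fit = qs.fit_multiple_qtl(bc_grid, y, [("chr1", 50.0), ("chr2", 50.0)])
        pcts.append(fit.pct_variance_full)
    assert np.mean(pcts) < 5.0


def test_adding_terms_never_decreases_variance(bc_grid, bc_phenotype):
    f1 = qs.fit_multiple_qtl(bc_grid, bc_phenotype, [("chr2", 55.0)])
    f2 = qs.fit_multiple_qtl(bc_grid, bc_phenotype, [("chr2", 55.0), ("chr1", 30.0)])
    f3 = qs.fit_multiple_qtl(
        bc_grid, bc_phenotype, [("chr2", 55.0), ("chr1", 30.0)], interactions=[(0, 1)]
    )
    assert f1.pct_variance_full <= f2.pct_variance_full + 1e-9
    assert f2.pct_variance_full <= f3.pct_variance_full + 1e-9


def test_rank_deficient_design_errors(bc_grid, bc_phenotype):
    with pytest.raises(ValueError, match="aliased|rank"):
        qs.fit_multiple_qtl(bc_grid, bc_phenotype, [("chr2", 55.0), ("chr2", 55.0)])
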