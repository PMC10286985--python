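"""Genotype-matrix construction: filtering, polarity, recombination, maps."""

import math

import numpy as np
import pandas as pd
import pytest

from lunaqtl import crossmap as cm, synthdata as sd

# --- VCF filtering ----------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _write_vcf(path, rows, n_samples=10):
    samples = "\t".join(f"s{i}" for i in range(n_samples))
    lines = [_VCF_HEADER.format(samples=samples)]
    for pos, gts in rows:
        fields = [f"{gt}:{gq}" for gt, gq in gts]
        lines.append(
            f"chr1\t{pos}\tv{pos}\tA\tC\t50\tPASS\t.\tGT:GQ\t" + "\t".join(fields) + "\n"
        )
    path.write_text("".join(lines))


def test_filter_variants_rules(tmp_path):
    """Five engineered sites: exactly two survive the GQ/MAF/missing rules."""
    het, hom_ref, hom_alt, miss = ("0/1", 60), ("0/0", 60), ("1/1", 60), ("./.", 0)
    low_gq_het = ("0/1", 5)
    rows = [
        # keep: 5 het, 5 hom-ref -> af 0.25
        (100, [het] * 5 + [hom_ref] * 5),
        # drop: 7/10 missing (0.7 > 0.6)
        (200, [het] * 3 + [miss] * 7),
        # drop: maf 1/20 = 0.05 < 0.10
        (300, [het] * 1 + [hom_ref] * 9),
        # keep: af = 10/20 = 0.5
        (400, [hom_alt] * 5 + [hom_ref] * 5),
        # drop: low GQ turns all hets missing -> monomorphic (maf 0)
        (500, [low_gq_het] * 4 + [hom_ref] * 6),
    ]
    vcf = tmp_path / "toy.vcf"
    _write_vcf(vcf, rows)
    calls, markers, dropped = cm.filter_variants(vcf)
    assert list(markers["position_bp"]) == [100, 400]
    assert dropped["missing"] == 1 and dropped["maf"] == 2
    assert calls.loc["s0", "v100"] == "AB"
    assert calls.loc["s0", "v400"] == "BB"


def test_filter_variants_drops_multiallelic(tmp_path):
    vcf = tmp_path / "multi.vcf"
    samples = "\t".join(f"s{i}" for i in range(4))
    vcf.write_text(
        _VCF_HEADER.format(samples=samples)
        + "chr1\t100\t.\tA\tC,G\t50\tPASS\t.\tGT:GQ\t"
        + "\t".join(["0/1:60"] * 4)
        + "\n"
    )
    _, markers, dropped = cm.filter_variants(vcf)
    assert len(markers) == 0 and dropped["multiallelic"] == 1


# --- informative markers ----------------------------------------------------


@pytest.mark.parametrize(
    "cross,p1,p2,kept",
    [
        ("F2", "AB", "AB", True),
        ("F2", "AA", "AB", False),
        ("BC", "AB", "AA", True),
        ("BC", "AB", "AB", True),
        ("BC", "AA", "AA", False),
    ],
)
def test_informative_marker_rule(cross, p1, p2, kept):
    parents = pd.DataFrame({"p1": [p1], "p2": [p2]}, index=["m1"])
    result, drops = cm.select_informative_markers(parents, cross)
    assert (len(result) == 1) == kept
    if kept and cross == "BC" and p2 == "AA":
        assert result.iloc[0]["expected_classes"] == {"AA": 0.5, "AB": 0.5}


def test_missing_parent_routed_ambiguous():
    parents = pd.DataFrame({"p1": ["AB"], "p2": ["-"]}, index=["m1"])
    result, drops = cm.select_informative_markers(parents, "F2")
    assert len(result) == 0 and "ambiguous" in drops[0][1]


# --- allele-origin consistency ----------------------------------------------


def _bc_matrix(cols: dict, parent_p2=None):
    ids = list(cols)
    markers = cm.MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ids,
                "chromosome": "chr1",
                "position_bp": np.arange(1, len(ids) + 1) * 1000,
            }
        )
    )
    calls = pd.DataFrame(cols, index=[f"i{k}" for k in range(len(next(iter(cols.values()))))])
    parents = None
    if parent_p2 is not None:
        parents = pd.DataFrame(
            {"f1": ["AB"] * len(ids), "p2": parent_p2}, index=ids
        )
    return cm.GenotypeMatrix("BC", markers, calls, parents)


def _f2_matrix(cols: dict):
    ids = list(cols)
    markers = cm.MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ids,
                "chromosome": "chr1",
                "position_bp": np.arange(1, len(ids) + 1) * 1000,
            }
        )
    )
    calls = pd.DataFrame(cols, index=[f"i{k}" for k in range(len(next(iter(cols.values()))))])
    return cm.GenotypeMatrix("F2", markers, calls)


def test_resolve_allele_origin_swaps_to_reduce_switches():
    """Two-marker toy: swapping marker 2 removes all 8 switches (oracle:
    both labelings enumerated by hand)."""
    m1 = ["AA"] * 4 + ["BB"] * 4
    m2_polarity_flipped = ["BB"] * 4 + ["AA"] * 4  # same haplotypes, labels swapped
    mat = _f2_matrix({"m1": m1, "m2": m2_polarity_flipped})
    resolved = cm.resolve_allele_origin(mat, ambiguous={"m2"})
    assert list(resolved.calls["m2"]) == m1
    before = cm.count_recombinations(mat, f2_double_counts_two=False).total_events
    after = cm.count_recombinations(resolved, f2_double_counts_two=False).total_events
    assert before == 8 and after == 0


def test_resolve_never_increases_switches():
    rng = np.random.default_rng(5)
    sim = sd.simulate_cross(sd.ArchitectureConfig(), "BC", 40, seed=17, with_emergence=False)
    mat = sim.matrix
    # randomly corrupt polarity of a third of the markers (not a chromosome's
    # first marker: without a left anchor its polarity is unrecoverable)
    calls = mat.calls.copy()
    swap = {"AA": "BB", "AB": "AB", "BB": "AA", "-": "-"}
    first = {mat.markers.chrom_markers(c)["marker_id"].iloc[0] for c in mat.markers.chromosomes}
    eligible = [m for m in calls.columns if m not in first]
    flipped = rng.choice(eligible, size=len(calls.columns) // 3, replace=False)
    for m in flipped:
        calls[m] = calls[m].map(swap)
    # BB introduced by the corruption: relabel matrix as F2-coded for counting
    corrupted = cm.GenotypeMatrix("F2", mat.markers, calls)
    resolved = cm.resolve_allele_origin(corrupted, ambiguous=set(flipped))
    before = cm.count_recombinations(corrupted, f2_double_counts_two=False).total_events
    after = cm.count_recombinations(resolved, f2_double_counts_two=False).total_events
    assert after <= before
    # and the corruption is fully undone: back to the true event count
    truth = cm.count_recombinations(
        cm.GenotypeMatrix("F2", mat.markers, mat.calls), f2_double_counts_two=False
    ).total_events
    assert after == truth


def test_resolve_all_missing_marker_unchanged():
    mat = _bc_matrix({"m1": ["AA", "AB"], "m2": ["-", "-"]}, parent_p2=["AA", "AB"])
    resolved = cm.resolve_allele_origin(mat)
    assert list(resolved.calls["m2"]) == ["-", "-"]


# --- recombination counting -------------------------------------------------


def test_count_single_event():
    mat = _bc_matrix({f"m{i}": v for i, v in enumerate([["AA"], ["AA"], ["AB"], ["AB"]])})
    rep = cm.count_recombinations(mat)
    assert rep.total_events == 1
    assert rep.intervals == [("chr1", "m1", "m2")]


def test_count_bridges_missing():
    mat = _bc_matrix({"m0": [["AA"]][0], "m1": ["-"], "m2": ["AB"]})
    rep = cm.count_recombinations(mat)
    assert rep.total_events == 1
    assert rep.intervals == [("chr1", "m0", "m2")]


def test_count_f2_double_transition():
    markers = cm.MarkerMap(
        pd.DataFrame({"marker_id": ["a", "b"], "chromosome": "chr1", "position_bp": [1, 2]})
    )
    calls = pd.DataFrame({"a": ["AA"], "b": ["BB"]}, index=["i0"])
    mat = cm.GenotypeMatrix("F2", markers, calls)
    assert cm.count_recombinations(mat).total_events == 2
    assert cm.count_recombinations(mat, f2_double_counts_two=False).total_events == 1


def test_count_toy_matrix_manual_enumeration():
    """Four BC individuals with hand-placed switches: totals by manual count."""
    cols = {
        "m0": ["AA", "AA", "AB", "AA"],
        "m1": ["AA", "AB", "AB", "AA"],
        "m2": ["AB", "AB", "AA", "AA"],
        "m3": ["AB", "AB", "AA", "AA"],
    }
    # i0: m1->m2 (1); i1: m0->m1 (1); i2: m1->m2 (1); i3: none  => 3 events
    rep = cm.count_recombinations(_bc_matrix(cols))
    assert rep.total_events == 3
    assert rep.per_individual_events == {"i0": 1, "i1": 1, "i2": 1, "i3": 0}
    assert rep.unique_breakpoint_positions == 2  # intervals (m0,m1) and (m1,m2)


def test_simulated_bc_event_count_exact():
    """Without genotyping error the observed switch count equals the true
    crossover count inside the marker span."""
    sim = sd.simulate_cross(sd.ArchitectureConfig(), "BC", 80, seed=23, with_emergence=False)
    rep = cm.count_recombinations(sim.matrix)
    # recompute the truth from the gamete patterns encoded in the calls
    truth = 0
    for chrom in sim.matrix.markers.chromosomes:
        ids = list(sim.matrix.markers.chrom_markers(chrom)["marker_id"])
        block = sim.matrix.calls[ids].to_numpy()
        truth += int((block[:, :-1] != block[:, 1:]).sum())
    assert rep.total_events == truth


def test_inversion_blocks_suppress_recombination():
    sim = sd.simulate_cross(
        sd.ArchitectureConfig(),
        "BC",
        200,
        seed=31,
        with_emergence=False,
        inversion_blocks=[("chr1", 20.0, 80.0)],
    )
    rep = cm.count_recombinations(sim.matrix)
    tbl = sim.matrix.markers.table
    pos = dict(zip(tbl["marker_id"], tbl["position_cM"]))
    for chrom, left, right in rep.intervals:
        if chrom == "chr1":
            assert not (20.0 <= pos[left] and pos[right] <= 80.0)


# --- genetic map ------------------------------------------------------------


def test_kosambi_closed_form_and_roundtrip():
    assert cm.kosambi_cm(0.0) == pytest.approx(0.0)
    assert float(cm.kosambi_cm(0.1)) == pytest.approx(10.14, abs=0.005)
    r = np.linspace(0.01, 0.45, 20)
    np.testing.assert_allclose(cm.kosambi_r(cm.kosambi_cm(r)), r, atol=1e-9)


@pytest.mark.parametrize("cross", ["BC", "F2"])
def test_map_length_converges(cross):
    """Kosambi map length of a simulated 110 cM chromosome is recovered
    within 10% at 500 meioses."""
    n = 500 if cross == "BC" else 250  # F2 has two informative meioses each
    sim = sd.simulate_cross(sd.ArchitectureConfig(), cross, n, seed=47, with_emergence=False)
    gmap = cm.build_genetic_map(sim.matrix)
    true_len = 110.0
    for chrom in ("chr1", "chr3"):  # chr2 carries the architecture locus too
        est = gmap.chrom_markers(chrom)["position_cM"].max()
        assert est == pytest.approx(true_len, rel=0.10)


def test_inversion_collapses_map_span():
    sim = sd.simulate_cross(
        sd.ArchitectureConfig(),
        "BC",
        300,
        seed=53,
        with_emergence=False,
        inversion_blocks=[("chr1", 20.0, 80.0)],
    )
    gmap = cm.build_genetic_map(sim.matrix)
    sub = gmap.chrom_markers("chr1")
    inside = sub[(sub["position_bp"] >= 20 * 400_000) & (sub["position_bp"] <= 80 * 400_000)]
    span = inside["position_cM"].max() - inside["position_cM"].min()
    assert span < 2.0  # ~60 physical cM collapse to ~0 genetic cM


def test_genotype_tsv_roundtrip(tmp_path):
    sim = sd.simulate_cross(sd.ArchitectureConfig(), "F2", 20, seed=61, with_emergence=False)
    p = tmp_path / "geno.tsv"
    cm.write_genotype_tsv(p, sim.matrix)
    back = cm.read_genotype_tsv(p, "F2")
    pd.testing.assert_frame_equal(
        back.calls, sim.matrix.calls, check_names=False
    )
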