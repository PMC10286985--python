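"""From genotype calls to mapping-ready cross matrices and genetic maps.

Covers variant filtering (GQ/MAF/missingness), selection of markers that are
informative in an F2 intercross or backcross, resolution of ambiguous A/B
allele polarity by along-chromosome consistency, recombination-event counting,
and Kosambi genetic-map construction from adjacent-marker recombination
fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "RecombinationReport",
    "filter_variants",
    "select_informative_markers",
    "resolve_allele_origin",
    "count_recombinations",
    "build_genetic_map",
    "kosambi_cm",
    "kosambi_r",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

log = logging.getLogger(__name__)

MISSING = "-"
CODES = ("AA", "AB", "BB")
_DOSAGE = {"AA": 2, "AB": 1, "BB": 0}


def kosambi_cm(r) -> np.ndarray:
    """Kosambi map distance in cM from recombination fraction r."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.49)
    return 100.0 * 0.25 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(cm) -> np.ndarray:
    """Recombination fraction from Kosambi cM (inverse of :func:`kosambi_cm`)."""
    d = np.asarray(cm, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


@dataclass
class MarkerMap:
    """Ordered markers with physical (bp, 1-based) and genetic (cM) positions."""

    table: pd.DataFrame  # marker_id, chromosome, position_bp[, position_cM]

    def __post_init__(self):
        req = {"marker_id", "chromosome", "position_bp"}
        if not req <= set(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(req)}")
        self.table = (
            self.table.sort_values(["chromosome", "position_bp"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def chromosomes(self):
        return list(dict.fromkeys(self.table["chromosome"]))

    def chrom_markers(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]


@dataclass
class GenotypeMatrix:
    """Coded cross genotypes: individuals x markers in {AA, AB, BB, '-'}.

    ``calls`` is indexed by individual with one column per marker_id, in map
    order.  ``parent_calls`` maps marker_id -> (F1/parent-1 call, parent-2
    call); for a BC the second entry is the recurrent parent.
    """

    cross_type: str  # "F2" or "BC"
    markers: MarkerMap
    calls: pd.DataFrame
    parent_calls: pd.DataFrame | None = None
    log_entries: list = field(default_factory=list)

    def __post_init__(self):
        if self.cross_type not in ("F2", "BC"):
            raise ValueError("cross_type must be 'F2' or 'BC'")
        order = list(self.markers.table["marker_id"])
        self.calls = self.calls[order]
        if self.cross_type == "BC" and (self.calls.to_numpy() == "BB").any():
            raise ValueError("BC matrix contains BB calls (non-recurrent homozygote)")

    @property
    def individuals(self):
        return list(self.calls.index)


@dataclass(frozen=True)
class RecombinationReport:
    per_individual_events: dict
    total_events: int
    unique_breakpoint_positions: int
    intervals: list  # (chromosome, left marker_id, right marker_id) with >=1 event


# ---------------------------------------------------------------------------
# VCF filtering


def filter_variants(vcf_path, min_gq: int = 20, maf: float = 0.10, max_missing: float = 0.60):
    """Filter a VCF to biallelic, well-genotyped, common sites.

    Genotypes with GQ below ``min_gq`` are set missing; sites with minor
    allele frequency below ``maf`` or a missing fraction above ``max_missing``
    are dropped, as are multiallelic sites.  Returns (DataFrame of calls coded
    AA/AB/BB/missing indexed by sample, marker table, drop-log dict).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    kept_calls, kept_markers = [], []
    dropped = {"multiallelic": 0, "maf": 0, "missing": 0, "malformed": 0}
    for var in vcf:
        try:
            if len(var.ALT) != 1:
                dropped["multiallelic"] += 1
                continue
            gts = np.array([g[:2] for g in var.genotypes], dtype=int)  # -1 = missing
            gq = var.gt_quals
            miss = (gts < 0).any(axis=1)
            if gq is not None:
                miss |= np.nan_to_num(gq, nan=-1.0) < min_gq
            alt_count = np.where(miss[:, None], 0, gts).sum()
            called = (~miss).sum()
            if called == 0 or miss.mean() > max_missing:
                dropped["missing"] += 1
                continue
            af = alt_count / (2 * called)
            if min(af, 1 - af) < maf:
                dropped["maf"] += 1
                continue
            codes = np.where(
                miss, MISSING, np.choose(gts.clip(min=0).sum(axis=1), ["AA", "AB", "BB"])
            )
            kept_calls.append(codes)
            kept_markers.append(
                {
                    "marker_id": var.ID or f"{var.CHROM}_{var.POS}",
                    "chromosome": var.CHROM,
                    "position_bp": var.POS,
                }
            )
        except Exception:  # malformed record: skip, count
            dropped["malformed"] += 1
    if dropped["malformed"]:
        log.warning("skipped %d malformed VCF records", dropped["malformed"])
    markers = pd.DataFrame(kept_markers)
    calls = pd.DataFrame(
        np.array(kept_calls).T if kept_calls else np.empty((len(samples), 0)),
        index=samples,
        columns=markers["marker_id"] if len(markers) else [],
    )
    return calls, markers, dropped


# ---------------------------------------------------------------------------
# Informative markers

_F2_CLASSES = {"AA": 0.25, "AB": 0.5, "BB": 0.25}
_BC_CLASSES = {"AA": 0.5, "AB": 0.5}


def select_informative_markers(parent_calls: pd.DataFrame, cross_type: str):
    """Keep markers whose parental genotypes make offspring segregation informative.

    F2: both F1 parents heterozygous (AB x AB).  BC: F1 heterozygous and the
    recurrent parent either heterozygous or homozygous (AB x AB or AB x hom).
    Returns a DataFrame marker_id, segregation class, expected offspring
    classes with Mendelian proportions; drop reasons are logged per marker.
    """
    if cross_type not in ("F2", "BC"):
        raise ValueError("cross_type must be 'F2' or 'BC'")
    kept, drops = [], []
    for marker_id, row in parent_calls.iterrows():
        p1, p2 = row.iloc[0], row.iloc[1]
        if MISSING in (p1, p2) or pd.isna(p1) or pd.isna(p2):
            drops.append((marker_id, "parental genotype missing (ambiguous)"))
            continue
        if cross_type == "F2":
            if p1 == "AB" and p2 == "AB":
                kept.append((marker_id, "ABxAB", _F2_CLASSES))
            else:
                drops.append((marker_id, f"uninformative in F2: {p1}x{p2}"))
        else:
            if p1 != "AB":
                drops.append((marker_id, f"F1 parent not heterozygous: {p1}"))
            elif p2 == "AB":
                kept.append((marker_id, "ABxAB", _F2_CLASSES))
            elif p2 in ("AA", "BB"):
                hom = p2
                het = "AB"
                kept.append((marker_id, f"ABx{hom}", {hom: 0.5, het: 0.5}))
            else:
                drops.append((marker_id, f"unrecognized parental call {p2}"))
    for marker_id, reason in drops:
        log.debug("dropped %s: %s", marker_id, reason)
    return (
        pd.DataFrame(kept, columns=["marker_id", "segregation", "expected_classes"]),
        drops,
    )


# ---------------------------------------------------------------------------
# Allele-origin consistency

_SWAP = {"AA": "BB", "AB": "AB", "BB": "AA", MISSING: MISSING}


def _switches(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Total genotype switches between two marker columns over individuals."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    return int((col_a[ok] != col_b[ok]).sum())


def resolve_allele_origin(matrix: GenotypeMatrix, ambiguous=None) -> GenotypeMatrix:
    """Fix A/B polarity of ambiguous markers by along-chromosome consistency.

    For every ambiguous marker (default: markers whose parental calls do not
    pin the polarity, i.e. both parents heterozygous, or no parental calls),
    choose identity or A<->B swap, left to right, so that the number of
    genotype switches against the nearest previously resolved marker is
    minimized over all individuals.  Ties keep the identity labeling.
    """
    calls = matrix.calls.copy()
    marker_tbl = matrix.markers.table
    if ambiguous is None:
        if matrix.parent_calls is not None:
            amb = {
                m
                for m, row in matrix.parent_calls.iterrows()
                if row.iloc[1] in ("AB", MISSING) or pd.isna(row.iloc[1])
            }
        else:
            amb = set(calls.columns)
    else:
        amb = set(ambiguous)

    decisions = []
    for chrom in matrix.markers.chromosomes:
        order = list(marker_tbl[marker_tbl["chromosome"] == chrom]["marker_id"])
        anchor = None
        for m in order:
            if m not in amb:
                anchor = m
                continue
            col = calls[m].to_numpy()
            if (col == MISSING).all():
                decisions.append((m, "all-missing", "identity"))
                continue
            if anchor is None:
                log.warning("chromosome %s has no anchor before %s: fixing identity", chrom, m)
                decisions.append((m, "no-anchor", "identity"))
                anchor = m
                continue
            ref = calls[anchor].to_numpy()
            swapped = np.vectorize(_SWAP.get)(col)
            if _switches(swapped, ref) < _switches(col, ref):
                calls[m] = swapped
                decisions.append((m, f"vs {anchor}", "swap"))
            else:
                decisions.append((m, f"vs {anchor}", "identity"))
            anchor = m
    out = GenotypeMatrix(
        cross_type=matrix.cross_type,
        markers=matrix.markers,
        calls=calls,
        parent_calls=matrix.parent_calls,
        log_entries=matrix.log_entries + decisions,
    )
    return out


# ---------------------------------------------------------------------------
# Recombination counting


def count_recombinations(matrix: GenotypeMatrix, f2_double_counts_two: bool = True) -> RecombinationReport:
    """Count genotype-switch events between consecutive non-missing calls.

    Missing calls are bridged: a switch across a gap is assigned to the
    interval between the flanking non-missing markers.  In an F2, an AA<->BB
    transition involves two recombinant gametes and by default counts as two
    events (``f2_double_counts_two``); set False to count it as one.
    """
    per_ind: dict = {}
    interval_hits: set = set()
    marker_tbl = matrix.markers.table
    for ind in matrix.individuals:
        events = 0
        for chrom in matrix.markers.chromosomes:
            order = list(marker_tbl[marker_tbl["chromosome"] == chrom]["marker_id"])
            row = matrix.calls.loc[ind, order].to_numpy()
            idx = np.flatnonzero(row != MISSING)
            for a, b in zip(idx[:-1], idx[1:]):
                if row[a] == row[b]:
                    continue
                if matrix.cross_type == "F2" and f2_double_counts_two:
                    n_ev = abs(_DOSAGE[row[a]] - _DOSAGE[row[b]])
                else:
                    n_ev = 1
                events += n_ev
                interval_hits.add((chrom, order[a], order[b]))
        per_ind[ind] = events
    return RecombinationReport(
        per_individual_events=per_ind,
        total_events=sum(per_ind.values()),
        unique_breakpoint_positions=len(interval_hits),
        intervals=sorted(interval_hits),
    )


# ---------------------------------------------------------------------------
# Genetic map


def _f2_joint_table(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities of two linked markers in an F2."""
    g = np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])  # AB, ab, Ab, aB gametes
    # gamete alleles at (locus1, locus2): A/ a coded 1/0
    al = np.array([(1, 1), (0, 0), (1, 0), (0, 1)])
    tab = np.zeros((3, 3))
    for i, (a1, a2) in enumerate(al):
        for j, (b1, b2) in enumerate(al):
            tab[2 - (a1 + b1), 2 - (a2 + b2)] += g[i] * g[j]  # row: AA,AB,BB at locus1
    return tab


def _estimate_r_f2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Maximum-likelihood adjacent recombination fraction from the 9-class table."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    if ok.sum() == 0:
        return 0.49
    ia = np.array([2 - _DOSAGE[c] for c in col_a[ok]])
    ib = np.array([2 - _DOSAGE[c] for c in col_b[ok]])
    counts = np.zeros((3, 3))
    np.add.at(counts, (ia, ib), 1)

    def nll(r):
        tab = np.clip(_f2_joint_table(r), 1e-12, None)
        return -float((counts * np.log(tab)).sum())

    res = minimize_scalar(nll, bounds=(1e-6, 0.49), method="bounded")
    return float(res.x)


def _estimate_r_bc(col_a: np.ndarray, col_b: np.ndarray) -> float:
    ok = (col_a != MISSING) & (col_b != MISSING)
    if ok.sum() == 0:
        return 0.49
    return float((col_a[ok] != col_b[ok]).mean())


def build_genetic_map(matrix: GenotypeMatrix) -> MarkerMap:
    """Kosambi cM positions from adjacent-marker recombination fractions.

    BC: r is the observed switch fraction between adjacent markers.  F2: r is
    the maximum-likelihood estimate from the 3x3 joint genotype table.
    Estimates at or above 0.5 are capped at 0.49 before the Kosambi transform.
    """
    tbl = matrix.markers.table.copy()
    est = _estimate_r_bc if matrix.cross_type == "BC" else _estimate_r_f2
    cm = np.zeros(len(tbl))
    for chrom in matrix.markers.chromosomes:
        sel = tbl.index[tbl["chromosome"] == chrom]
        order = list(tbl.loc[sel, "marker_id"])
        if len(order) < 2:
            continue
        pos = 0.0
        for k in range(1, len(order)):
            a = matrix.calls[order[k - 1]].to_numpy()
            b = matrix.calls[order[k]].to_numpy()
            r = est(a, b)
            if r >= 0.5:
                log.warning("r >= 0.5 between %s and %s: capped", order[k - 1], order[k])
            pos += float(kosambi_cm(r))
            cm[sel[k]] = pos
    tbl["position_cM"] = cm
    return MarkerMap(tbl)


# ---------------------------------------------------------------------------
# TSV dialect (marker rows, individual columns)


def write_genotype_tsv(path, matrix: GenotypeMatrix) -> None:
    tbl = matrix.markers.table.set_index("marker_id")
    out = pd.concat([tbl, matrix.calls.T], axis=1)
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


def read_genotype_tsv(path, cross_type: str, parent_calls: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="marker_id")
    meta_cols = [c for c in ("chromosome", "position_bp", "position_cM") if c in df.columns]
    markers = MarkerMap(df[meta_cols].reset_index())
    calls = df.drop(columns=meta_cols).T
    calls = calls.where(~calls.isna(), MISSING)
    return GenotypeMatrix(cross_type=cross_type, markers=markers, calls=calls, parent_calls=parent_calls)
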