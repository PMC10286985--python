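"""Forward simulation of strains, crosses, and emergence data.

Generates data with the statistical structure the analysis assumes: two
parental strains — one sensitive to the zeitgeber (unimodal von Mises
emergence peak on the cycle) and one insensitive (uniform emergence) — F1/F2/
backcross families segregating recessive insensitivity at one or more loci,
marker maps on three chromosomes with optional non-recombining inversion
blocks, and a sex locus for validating binary-phenotype mapping.

Meioses follow a Haldane (no-interference) model: crossover counts are
Poisson in the map length, positions uniform in cM outside inversion blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossmap import GenotypeMatrix, MarkerMap

__all__ = [
    "StrainModel",
    "Locus",
    "ArchitectureConfig",
    "SimulatedCross",
    "make_marker_map",
    "simulate_meiosis",
    "simulate_cross",
    "simulate_emergence",
    "simulate_strain_emergence",
    "SENSITIVE_DEFAULT",
    "INSENSITIVE_DEFAULT",
]


@dataclass(frozen=True)
class StrainModel:
    """Emergence model of a parental strain on the zeitgeber cycle.

    Sensitive strains emerge in a von Mises peak at ``peak_day`` with
    concentration ``kappa``; insensitive strains are uniform (kappa = 0).
    """

    sensitivity: str  # "sensitive" | "insensitive"
    peak_day: float = 12.0
    kappa: float = 2.6
    period: int = 15

    def __post_init__(self):
        if self.sensitivity == "insensitive" and self.kappa != 0.0:
            object.__setattr__(self, "kappa", 0.0)
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


# kappa = 2.6 gives a mean resultant length around 0.77, the rhythm strength
# of a strongly entrained sensitive strain; insensitive strains are uniform.
SENSITIVE_DEFAULT = StrainModel("sensitive", peak_day=12.0, kappa=2.6, period=15)
INSENSITIVE_DEFAULT = StrainModel("insensitive", peak_day=12.0, kappa=0.0, period=15)


@dataclass(frozen=True)
class Locus:
    chromosome: str
    cM: float
    mode: str = "recessive_insensitive"  # or "additive"
    # penetrance keyed by count of insensitive-parent alleles (0, 1, 2)
    penetrance: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if any(not 0 <= p <= 1 for p in self.penetrance):
            raise ValueError("penetrance values must lie in [0, 1]")
        if self.mode == "recessive_insensitive" and (
            self.penetrance[0] > 0 or self.penetrance[1] > 0
        ):
            raise ValueError("recessive mode allows elevated penetrance only for homozygotes")


@dataclass
class ArchitectureConfig:
    """Genetic architecture of insensitivity: causal loci and epistasis.

    Single-locus penetrances combine by noisy-OR (insensitivity arises if any
    causal locus expresses it); ``epistatic_pairs`` maps a pair of locus
    indices to a penetrance table keyed by the two loci's insensitive-allele
    counts, overriding the marginal combination for those loci.
    """

    loci: list = field(default_factory=lambda: [Locus("chr2", 55.0)])
    epistatic_pairs: dict = field(default_factory=dict)


@dataclass
class SimulatedCross:
    matrix: GenotypeMatrix
    architecture: ArchitectureConfig
    true_insensitive: np.ndarray  # bool per progeny
    sex: pd.Series | None
    emergence: pd.DataFrame | None
    seed: int
    truth: dict = field(default_factory=dict)


def make_marker_map(
    n_chromosomes: int = 3,
    markers_per_chromosome: int = 45,
    spacing_cM: float = 2.5,
    bp_per_cM: int = 400_000,
) -> MarkerMap:
    """Regular marker map: default 3 chromosomes x 45 markers at 2.5 cM (~110 cM each)."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for m in range(markers_per_chromosome):
            cm = m * spacing_cM
            rows.append(
                {
                    "marker_id": f"chr{c}_m{m:03d}",
                    "chromosome": f"chr{c}",
                    "position_bp": int(cm * bp_per_cM) + 1,
                    "position_cM": cm,
                }
            )
    return MarkerMap(pd.DataFrame(rows))


def _allowed_segments(length: float, blocks) -> list:
    """Non-inversion cM segments of [0, length]."""
    segs, cur = [], 0.0
    for lo, hi in sorted(blocks):
        lo, hi = max(lo, 0.0), min(hi, length)
        if lo > cur:
            segs.append((cur, lo))
        cur = max(cur, hi)
    if cur < length:
        segs.append((cur, length))
    return segs or [(0.0, 0.0)]


def _draw_positions(k: int, segments, rng) -> np.ndarray:
    lens = np.array([hi - lo for lo, hi in segments])
    total = lens.sum()
    if total <= 0 or k == 0:
        return np.empty(0)
    u = rng.uniform(0, total, size=k)
    edges = np.concatenate([[0.0], np.cumsum(lens)])
    seg_idx = np.searchsorted(edges, u, side="right") - 1
    return np.array([segments[s][0] + (u[i] - edges[s]) for i, s in enumerate(seg_idx)])


def simulate_meiosis(haplotypes: np.ndarray, pos_cM: np.ndarray, rng, inversion_spans=()) -> np.ndarray:
    """One gamete from a diploid parent on one chromosome.

    ``haplotypes`` is (2, m) alleles; crossover count ~ Poisson(map length in
    Morgans); positions uniform in cM outside ``inversion_spans``; the gamete
    alternates parental phase at each crossover.
    """
    pos = np.asarray(pos_cM, dtype=float)
    length = float(pos.max() - pos.min()) if len(pos) > 1 else 0.0
    n_x = rng.poisson(length / 100.0) if length > 0 else 0
    xpos = _draw_positions(n_x, _allowed_segments(length, inversion_spans), rng) + pos.min()
    start = rng.integers(0, 2)
    phase = (start + np.searchsorted(np.sort(xpos), pos - pos.min() + pos.min(), side="right")) % 2
    return haplotypes[phase, np.arange(len(pos))]


def _f1_gametes(pos_cM: np.ndarray, n_gametes: int, rng, inversion_spans=()) -> np.ndarray:
    """Batch of F1 gametes coded as the insensitive-parent allele (0/1).

    An F1 from fully homozygous parents carries one all-0 and one all-1
    haplotype, so the gamete equals the phase pattern of the meiosis.
    """
    pos = np.asarray(pos_cM, dtype=float)
    m = len(pos)
    length = float(pos.max() - pos.min()) if m > 1 else 0.0
    out = np.empty((n_gametes, m), dtype=np.int8)
    counts = rng.poisson(length / 100.0, size=n_gametes) if length > 0 else np.zeros(n_gametes, int)
    starts = rng.integers(0, 2, size=n_gametes)
    segs = _allowed_segments(length, inversion_spans)
    rel = pos - pos.min()
    for g in range(n_gametes):
        if counts[g] == 0:
            out[g] = starts[g]
            continue
        xpos = np.sort(_draw_positions(counts[g], segs, rng))
        out[g] = (starts[g] + np.searchsorted(xpos, rel, side="right")) % 2
    return out


_F2_CODE = np.array(["BB", "AB", "AA"])  # indexed by count of A (sensitive) alleles
_BC_CODE = np.array(["AB", "AA"])  # indexed by count of recurrent alleles - 1


def simulate_cross(
    architecture: ArchitectureConfig,
    cross_type: str,
    n: int,
    seed: int,
    marker_map: MarkerMap | None = None,
    inversion_blocks=(),
    sex_locus: tuple | None = None,
    sensitive_strain: StrainModel = SENSITIVE_DEFAULT,
    insensitive_strain: StrainModel = INSENSITIVE_DEFAULT,
    with_emergence: bool = True,
    missing_rate: float = 0.0,
) -> SimulatedCross:
    """Simulate an F2 intercross or a backcross to the insensitive parent.

    Parent 1 (sensitive) contributes the 'A' allele, parent 2 (insensitive)
    the 'B' allele.  In the BC (F1 x insensitive parent) genotypes are coded
    relative to the recurrent parent: recurrent homozygote -> AA, het -> AB,
    so the matrix contains no BB calls.  Each progeny's latent insensitivity
    is drawn by penetrance given its genotype at the architecture loci;
    ``inversion_blocks`` is a list of (chromosome, lo_cM, hi_cM) spans with
    recombination suppressed.
    """
    if cross_type not in ("F2", "BC"):
        raise ValueError("cross_type must be 'F2' or 'BC'")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    gmap = marker_map or make_marker_map()
    tbl = gmap.table

    for loc in architecture.loci:
        if loc.chromosome not in gmap.chromosomes:
            raise ValueError(f"architecture locus on unknown chromosome {loc.chromosome!r}")
        sub = tbl[tbl["chromosome"] == loc.chromosome]
        if not (sub["position_cM"].min() - 1e-9 <= loc.cM <= sub["position_cM"].max() + 1e-9):
            raise ValueError(f"architecture locus at {loc.cM} cM is off the map")

    # insensitive-allele counts per marker, n x m, built chromosome-wise
    counts_cols, code_cols = [], []
    for chrom in gmap.chromosomes:
        sub = tbl[tbl["chromosome"] == chrom]
        pos = sub["position_cM"].to_numpy()
        spans = [(lo, hi) for c, lo, hi in inversion_blocks if c == chrom]
        gam1 = _f1_gametes(pos, n, rng, spans)
        if cross_type == "F2":
            gam2 = _f1_gametes(pos, n, rng, spans)
        else:
            gam2 = np.ones((n, len(pos)), dtype=np.int8)  # recurrent insensitive parent
        counts_cols.append(gam1 + gam2)
    b_count = np.concatenate(counts_cols, axis=1)  # insensitive-allele count 0..2

    if cross_type == "F2":
        codes = _F2_CODE[2 - b_count]
    else:
        codes = _BC_CODE[2 - b_count]  # b_count in {1, 2}
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes = np.where(mask, "-", codes)

    individuals = [f"{cross_type}_{i:04d}" for i in range(n)]
    calls = pd.DataFrame(codes, index=individuals, columns=list(tbl["marker_id"]))
    if cross_type == "F2":
        parent_calls = pd.DataFrame(
            {"p1": ["AB"] * len(tbl), "p2": ["AB"] * len(tbl)}, index=tbl["marker_id"]
        )
    else:
        parent_calls = pd.DataFrame(
            {"f1": ["AB"] * len(tbl), "recurrent": ["AA"] * len(tbl)}, index=tbl["marker_id"]
        )
    matrix = GenotypeMatrix(cross_type=cross_type, markers=gmap, calls=calls, parent_calls=parent_calls)

    marker_ids = list(tbl["marker_id"])

    def locus_counts(chrom, cm) -> np.ndarray:
        sub = tbl[tbl["chromosome"] == chrom]
        j = (sub["position_cM"] - cm).abs().idxmin()
        return b_count[:, marker_ids.index(tbl.loc[j, "marker_id"])]

    # penetrance: noisy-OR over loci, epistatic pairs override their members
    in_pair = {i for pair in architecture.epistatic_pairs for i in pair}
    p_not = np.ones(n)
    for i, loc in enumerate(architecture.loci):
        if i in in_pair:
            continue
        pen = np.asarray(loc.penetrance)[locus_counts(loc.chromosome, loc.cM)]
        p_not *= 1.0 - pen
    for (a, b), table in architecture.epistatic_pairs.items():
        ca = locus_counts(architecture.loci[a].chromosome, architecture.loci[a].cM)
        cb = locus_counts(architecture.loci[b].chromosome, architecture.loci[b].cM)
        pen = np.array([table[(x, y)] for x, y in zip(ca, cb)])
        p_not *= 1.0 - pen
    p_insens = 1.0 - p_not
    true_insensitive = rng.random(n) < p_insens

    sex = None
    if sex_locus is not None:
        het = locus_counts(*sex_locus) == 1
        sex = pd.Series(np.where(het, "M", "F"), index=individuals)

    emergence = None
    if with_emergence:
        emergence = simulate_emergence(
            true_insensitive, sensitive_strain, insensitive_strain, rng, individuals
        )

    return SimulatedCross(
        matrix=matrix,
        architecture=architecture,
        true_insensitive=true_insensitive,
        sex=sex,
        emergence=emergence,
        seed=seed,
        truth={
            "loci": [(l.chromosome, l.cM, l.mode) for l in architecture.loci],
            "n": n,
            "cross_type": cross_type,
            "true_insensitive_fraction": float(true_insensitive.mean()),
            "seed": seed,
        },
    )


def _von_mises_days(n: int, strain: StrainModel, rng) -> np.ndarray:
    """Integer lunar days 1..period from the strain's emergence model."""
    period = strain.period
    if strain.kappa == 0.0:
        return rng.integers(1, period + 1, size=n)
    mu = 2.0 * np.pi * strain.peak_day / period
    ang = rng.vonmises(mu, strain.kappa, size=n)
    day = np.rint(np.mod(ang, 2 * np.pi) / (2 * np.pi) * period).astype(int)
    day[day == 0] = period  # day boundary wraps period <-> 0
    return day


def simulate_emergence(
    states,
    sensitive_strain: StrainModel,
    insensitive_strain: StrainModel,
    rng_or_seed,
    individuals=None,
    n_cycles: int = 2,
    family: str = "sim",
) -> pd.DataFrame:
    """Emergence table for progeny with known latent sensitivity states.

    Sensitive individuals draw a von Mises day; insensitive ones a uniform
    day.  Experimental days spread the emergence over ``n_cycles`` zeitgeber
    cycles with the day-1 anchor at experimental day 1.
    """
    rng = np.random.default_rng(rng_or_seed) if isinstance(rng_or_seed, (int, np.integer)) else rng_or_seed
    states = np.asarray(states, dtype=bool)
    n = len(states)
    period = sensitive_strain.period
    days = np.empty(n, dtype=int)
    days[~states] = _von_mises_days(int((~states).sum()), sensitive_strain, rng)
    days[states] = _von_mises_days(int(states.sum()), insensitive_strain, rng)
    cycle = rng.integers(0, n_cycles, size=n)
    if individuals is None:
        individuals = [f"ind_{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "family": family,
            "individual": individuals,
            "experimental_day": days + period * cycle,
            "sex": "unknown",
            "count": 1,
            "lunar_day": days,
        }
    )


def simulate_strain_emergence(strain: StrainModel, n: int, seed, family: str = "strain") -> pd.DataFrame:
    """Emergence table of a pure parental strain (all individuals share its model)."""
    states = np.full(n, strain.sensitivity == "insensitive")
    return simulate_emergence(states, strain, strain, np.random.default_rng(seed), family=family)
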