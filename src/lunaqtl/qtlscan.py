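"""Interval mapping for probability and binary phenotypes.

The engine follows the classical single-QTL interval-mapping scaffold: hidden
Markov conditional genotype probabilities on a cM grid, Haley-Knott regression
of the phenotype on expected genotype dosages (quantitative model) or a
logistic likelihood-ratio (binary model), genome-wide significance by
phenotype permutation (default 1000 permutations, 5% cutoff), Bayesian
credible intervals from the normalized 10^LOD profile, composite interval
mapping with backward-selected marker cofactors, a two-locus scan separating
full (LODf) from interaction (LODi) evidence, and a multiple-QTL joint fit
with drop-one variance decomposition.

Quantitative LOD: (n/2) * log10(RSS0 / RSS1).  Binary LOD: (LL1 - LL0)/ln 10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossmap import GenotypeMatrix, MarkerMap, kosambi_r, MISSING

__all__ = [
    "PositionGrid",
    "ScanResult",
    "PairScanResult",
    "MultiQtlFit",
    "genotype_probabilities",
    "scan_single",
    "permutation_threshold",
    "bayes_interval",
    "cim_scan",
    "scan_pairs",
    "fit_multiple_qtl",
]

log = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass
class PositionGrid:
    """Conditional genotype-class probabilities on a cM position grid.

    ``probs`` has shape (n_individuals, n_positions, n_classes); classes are
    (AA, AB) for a backcross and (AA, AB, BB) for an intercross, and the
    probabilities sum to one per individual and position.
    """

    cross_type: str
    positions: pd.DataFrame  # chromosome, pos_cM, marker_id (or "")
    probs: np.ndarray
    individuals: list
    error_rate: float = 1e-4

    @property
    def n_classes(self) -> int:
        return 2 if self.cross_type == "BC" else 3

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def chrom_slice(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.positions["chromosome"] == chrom).to_numpy())

    def genetic_design(self) -> np.ndarray:
        """Per-position genetic predictor columns, shape (P, n, k).

        BC: one column, the expected dosage of the non-recurrent allele.
        F2: additive (expected A-allele dosage, centered scale -1..1) and
        dominance (P(AB)) columns.
        """
        pr = self.probs  # (n, P, c)
        if self.cross_type == "BC":
            x = pr[:, :, 1]  # P(AB)
            out = x.T[:, :, None]
        else:
            add = pr[:, :, 0] - pr[:, :, 2]  # P(AA) - P(BB)
            dom = pr[:, :, 1]
            out = np.stack([add.T, dom.T], axis=2)
        return np.ascontiguousarray(out)


@dataclass
class ScanResult:
    table: pd.DataFrame  # chromosome, pos_cM, lod
    model: str
    peak_chromosome: object = None
    peak_cM: float = 0.0
    max_lod: float = 0.0
    threshold: float | None = None
    interval: tuple | None = None  # (chromosome, lo_cM, hi_cM)

    def __post_init__(self):
        i = int(self.table["lod"].idxmax())
        self.peak_chromosome = self.table.loc[i, "chromosome"]
        self.peak_cM = float(self.table.loc[i, "pos_cM"])
        self.max_lod = float(self.table.loc[i, "lod"])


@dataclass
class PairScanResult:
    positions: pd.DataFrame
    lod_full: np.ndarray  # (P, P), upper triangle filled
    lod_add: np.ndarray
    lod_int: np.ndarray
    peak_full: tuple
    peak_int: tuple


@dataclass
class MultiQtlFit:
    terms: list
    pct_variance_full: float
    pct_variance_per_term: list
    f_stats: list
    p_values: list
    lod_full: float
    n: int


# ---------------------------------------------------------------------------
# Hidden-Markov genotype probabilities


def _transition(r: float, cross_type: str) -> np.ndarray:
    if cross_type == "BC":
        return np.array([[1 - r, r], [r, 1 - r]])
    s = 1 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


_CODE_INDEX = {"AA": 0, "AB": 1, "BB": 2}


def genotype_probabilities(
    matrix: GenotypeMatrix,
    genetic_map: MarkerMap | None = None,
    step_cM: float = 1.0,
    error_rate: float = 1e-4,
) -> PositionGrid:
    """Conditional genotype-class probabilities given flanking markers.

    A forward-backward pass per chromosome with transition probabilities from
    the inverse-Kosambi recombination fraction of each cM gap and a symmetric
    genotyping-error emission model with rate ``error_rate``.  The grid holds
    every marker plus pseudo-positions every ``step_cM`` (``step_cM=None`` for
    markers only).
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    gmap = genetic_map or matrix.markers
    tbl = gmap.table
    if "position_cM" not in tbl.columns:
        raise ValueError("genetic map has no position_cM; run build_genetic_map")
    cross = matrix.cross_type
    k = 2 if cross == "BC" else 3
    prior = np.array([0.5, 0.5]) if cross == "BC" else np.array([0.25, 0.5, 0.25])
    inds = matrix.individuals
    n = len(inds)

    pos_rows = []
    prob_chunks = []
    for chrom in gmap.chromosomes:
        sub = tbl[tbl["chromosome"] == chrom]
        if len(sub) == 0:
            log.warning("empty chromosome %s skipped", chrom)
            continue
        m_pos = sub["position_cM"].to_numpy(dtype=float)
        m_ids = list(sub["marker_id"])
        if step_cM:
            grid = np.arange(m_pos.min(), m_pos.max() + 1e-9, step_cM)
            pos = np.unique(np.round(np.concatenate([m_pos, grid]), 6))
        else:
            pos = np.unique(np.round(m_pos, 6))
        P = len(pos)
        marker_at = {}
        for mid, mp in zip(m_ids, m_pos):
            j = int(np.argmin(np.abs(pos - mp)))
            marker_at.setdefault(j, []).append(mid)

        # emission[n, P, k]
        emis = np.ones((n, P, k))
        for j, mids in marker_at.items():
            for mid in mids:
                obs = matrix.calls[mid].to_numpy()
                for ci, ind in enumerate(inds):
                    o = obs[ci]
                    if o == MISSING:
                        continue
                    oi = _CODE_INDEX[o]
                    if cross == "BC" and oi == 2:
                        oi = 1  # defensive; BB impossible in BC
                    e = np.full(k, error_rate / (k - 1)) if error_rate > 0 else np.zeros(k)
                    e[oi] = 1.0 - error_rate
                    emis[ci, j, :] *= e

        trans = [
            _transition(float(kosambi_r(pos[j + 1] - pos[j])), cross) for j in range(P - 1)
        ]
        alpha = np.zeros((n, P, k))
        beta = np.ones((n, P, k))
        a = prior[None, :] * emis[:, 0, :]
        norm = a.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        alpha[:, 0, :] = a / norm
        for j in range(1, P):
            a = (alpha[:, j - 1, :] @ trans[j - 1]) * emis[:, j, :]
            norm = a.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            alpha[:, j, :] = a / norm
        for j in range(P - 2, -1, -1):
            b = (beta[:, j + 1, :] * emis[:, j + 1, :]) @ trans[j].T
            norm = b.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            beta[:, j, :] = b / norm
        post = alpha * beta
        norm = post.sum(axis=2, keepdims=True)
        norm[norm == 0] = 1.0
        post /= norm

        prob_chunks.append(post)
        for j, p in enumerate(pos):
            mids = marker_at.get(j, [])
            pos_rows.append({"chromosome": chrom, "pos_cM": float(p), "marker_id": mids[0] if mids else ""})

    positions = pd.DataFrame(pos_rows)
    probs = np.concatenate(prob_chunks, axis=1)
    return PositionGrid(
        cross_type=cross,
        positions=positions,
        probs=probs,
        individuals=inds,
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# LOD machinery


def _with_intercept(cov: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if cov is not None:
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.append(cov)
    return np.concatenate(cols, axis=1)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _hk_lod_profile(G: np.ndarray, Y: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
    """Haley-Knott LOD, vectorized over phenotypes.

    G: (P, n, k) genetic design; Y: (B, n) phenotypes.  Returns (B, P).
    """
    P, n, k = G.shape
    Y = np.atleast_2d(Y)
    X0 = _with_intercept(cov, n)
    Q0, _ = np.linalg.qr(X0)
    rss0 = (Y**2).sum(axis=1) - ((Y @ Q0) ** 2).sum(axis=1)  # (B,)
    # full design per position: [X0 | G_p] -> orthonormalize
    X = np.concatenate([np.broadcast_to(X0, (P, n, X0.shape[1])), G], axis=2)
    Q, _ = np.linalg.qr(X)  # (P, n, q)
    proj = np.einsum("pnq,bn->bpq", Q, Y)
    rss1 = (Y**2).sum(axis=1)[:, None] - (proj**2).sum(axis=2)  # (B, P)
    rss1 = np.clip(rss1, 1e-12, None)
    rss0 = np.clip(rss0, 1e-12, None)
    return np.clip(0.5 * n * np.log10(rss0[:, None] / rss1), 0.0, None)


def _logistic_ll(X: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8) -> float:
    """Log-likelihood of a logistic fit (Newton-Raphson with ridge guard)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(k)
        step = np.linalg.solve(H, grad)
        beta += step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _logistic_lod_profile(G: np.ndarray, y: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
    P, n, k = G.shape
    X0 = _with_intercept(cov, n)
    ll0 = _logistic_ll(X0, y)
    lods = np.empty(P)
    for p in range(P):
        X = np.concatenate([X0, G[p]], axis=1)
        lods[p] = (_logistic_ll(X, y) - ll0) / _LN10
    return np.clip(lods, 0.0, None)


def scan_single(
    grid: PositionGrid,
    phenotype,
    model: str = "quantitative",
    covariates=None,
) -> ScanResult:
    """Genome scan for a single QTL.

    ``model='quantitative'``: Haley-Knott regression on expected genotype
    dosages, LOD = (n/2) log10(RSS0/RSS1).  ``model='binary'``: logistic
    likelihood-ratio, LOD = (LL1 - LL0)/ln 10; phenotype must be 0/1.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("degenerate phenotype: zero variance")
    G = grid.genetic_design()
    if model == "quantitative":
        lod = _hk_lod_profile(G, y[None, :], covariates)[0]
    elif model == "binary":
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("binary model requires phenotype values in {0, 1}")
        lod = _logistic_lod_profile(G, y, covariates)
    else:
        raise ValueError("model must be 'quantitative' or 'binary'")
    table = grid.positions[["chromosome", "pos_cM"]].copy()
    table["lod"] = lod
    return ScanResult(table=table, model=model)


def permutation_threshold(
    grid: PositionGrid,
    phenotype,
    model: str = "quantitative",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    covariates=None,
    chunk: int = 200,
) -> float:
    """Genome-wide significance threshold by phenotype permutation.

    The (1 - alpha) quantile of the maximum LOD over ``n_perm`` permutations
    of the phenotype vector (covariates, if any, stay attached to genotypes).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    G = grid.genetic_design()
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        Y = np.stack([rng.permutation(y) for _ in range(b)])
        if model == "quantitative":
            lods = _hk_lod_profile(G, Y, covariates)
        else:
            lods = np.stack([_logistic_lod_profile(G, Y[i], covariates) for i in range(b)])
        maxima[done : done + b] = lods.max(axis=1)
        done += b
    if alpha >= 1.0:
        return float(maxima.min())
    return float(np.quantile(maxima, 1.0 - alpha))


def bayes_interval(scan: ScanResult, chromosome, prob: float = 0.95) -> tuple:
    """Bayesian credible interval from the normalized 10^LOD profile.

    10^LOD over the chromosome's grid is treated as an unnormalized density;
    starting from the peak, the interval grows toward the higher-mass neighbor
    until it holds at least ``prob`` of the mass.  A flat profile returns the
    whole chromosome (flagged by covering its full span).
    """
    sub = scan.table[scan.table["chromosome"] == chromosome].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no scan positions on chromosome {chromosome!r}")
    pos = sub["pos_cM"].to_numpy()
    dens = np.power(10.0, sub["lod"].to_numpy() - sub["lod"].max())
    dens = dens / dens.sum()
    if np.allclose(dens, dens[0]):
        return float(pos[0]), float(pos[-1])
    peak = int(np.argmax(dens))
    lo = hi = peak
    mass = dens[peak]
    while mass < prob:
        left = dens[lo - 1] if lo > 0 else -1.0
        right = dens[hi + 1] if hi < len(dens) - 1 else -1.0
        if left < 0 and right < 0:
            break
        if right >= left:
            hi += 1
            mass += dens[hi]
        else:
            lo -= 1
            mass += dens[lo]
    return float(pos[lo]), float(pos[hi])


# ---------------------------------------------------------------------------
# Composite interval mapping


def _marker_positions(grid: PositionGrid) -> np.ndarray:
    return np.flatnonzero((grid.positions["marker_id"] != "").to_numpy())


def cim_scan(
    grid: PositionGrid,
    phenotype,
    n_cofactors: int = 5,
    window_cM: float = 10.0,
    candidate_pool: int = 30,
) -> ScanResult:
    """Composite interval mapping: single-QTL scan with marker cofactors.

    Cofactors are chosen by backward elimination (smallest-|t| first) from the
    ``candidate_pool`` markers with the strongest single-marker association,
    down to ``n_cofactors``.  At each test position, cofactors within
    ``window_cM`` of the position on the same chromosome are excluded from
    the model.  ``n_cofactors=0`` reduces to :func:`scan_single`.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("degenerate phenotype: zero variance")
    G = grid.genetic_design()
    if n_cofactors == 0:
        return scan_single(grid, y, model="quantitative")

    m_idx = _marker_positions(grid)
    if len(m_idx) < n_cofactors:
        raise ValueError("fewer markers than requested cofactors")
    single = _hk_lod_profile(G[m_idx], y[None, :])[0]
    pool = list(m_idx[np.argsort(single)[::-1][:candidate_pool]])

    def dosage_cols(idx_list):
        if not idx_list:
            return None
        return np.concatenate([G[j] for j in idx_list], axis=1)

    active = list(pool)
    while len(active) > n_cofactors:
        X = _with_intercept(dosage_cols(active), len(y))
        rank = np.linalg.matrix_rank(X)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - rank, 1)
        sigma2 = float(resid @ resid) / dof
        XtX = X.T @ X + 1e-10 * np.eye(X.shape[1])
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(XtX)) * sigma2, 1e-20, None))
        tvals = np.abs(beta / se)
        # per cofactor, smallest max-|t| over its columns; column 0 is intercept
        k = G.shape[2]
        scores = [tvals[1 + i * k : 1 + (i + 1) * k].max() for i in range(len(active))]
        active.pop(int(np.argmin(scores)))

    cof_pos = grid.positions.iloc[active]
    lods = np.empty(grid.n_positions)
    pos_tbl = grid.positions
    for p in range(grid.n_positions):
        chrom = pos_tbl.iloc[p]["chromosome"]
        cm = pos_tbl.iloc[p]["pos_cM"]
        keep = [
            j
            for j, (cchrom, ccm) in zip(active, zip(cof_pos["chromosome"], cof_pos["pos_cM"]))
            if not (cchrom == chrom and abs(ccm - cm) <= window_cM)
        ]
        cov = dosage_cols(keep)
        X0 = _with_intercept(cov, len(y))
        X1 = np.concatenate([X0, G[p]], axis=1)
        rss0, rss1 = _rss(X0, y), max(_rss(X1, y), 1e-12)
        lods[p] = max(0.5 * len(y) * math.log10(rss0 / rss1), 0.0)
    table = pos_tbl[["chromosome", "pos_cM"]].copy()
    table["lod"] = lods
    return ScanResult(table=table, model="cim")


# ---------------------------------------------------------------------------
# Two-locus scan


def _coarse_positions(grid: PositionGrid, step: float) -> np.ndarray:
    keep = []
    for chrom in grid.positions["chromosome"].unique():
        idx = grid.chrom_slice(chrom)
        pos = grid.positions["pos_cM"].to_numpy()[idx]
        last = -np.inf
        for j, p in zip(idx, pos):
            if p - last >= step - 1e-9:
                keep.append(j)
                last = p
    return np.array(keep)


def scan_pairs(grid: PositionGrid, phenotype, step_cM: float = 2.5) -> PairScanResult:
    """Two-locus scan on a coarse grid: LODf (full vs null) and LODi (vs additive).

    For each position pair, three nested regressions are compared: the null
    (intercept), the additive two-locus model, and the full model with
    locus-by-locus interaction terms.  LODi = LODf - LOD(additive vs null).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("degenerate phenotype: zero variance")
    sel = _coarse_positions(grid, step_cM)
    G = grid.genetic_design()[sel]
    P, n, k = G.shape
    rss0 = float(np.sum((y - y.mean()) ** 2))
    lod_f = np.zeros((P, P))
    lod_a = np.zeros((P, P))
    ones = np.ones((n, 1))
    for i in range(P):
        for j in range(i + 1, P):
            gi, gj = G[i], G[j]
            inter = np.einsum("nk,nl->nkl", gi, gj).reshape(n, k * k)
            Xa = np.concatenate([ones, gi, gj], axis=1)
            Xf = np.concatenate([Xa, inter], axis=1)
            ra = max(_rss(Xa, y), 1e-12)
            rf = max(_rss(Xf, y), 1e-12)
            lod_a[i, j] = max(0.5 * n * math.log10(rss0 / ra), 0.0)
            lod_f[i, j] = max(0.5 * n * math.log10(rss0 / rf), 0.0)
    lod_i = np.clip(lod_f - lod_a, 0.0, None)
    positions = grid.positions.iloc[sel].reset_index(drop=True)

    def argpeak(m):
        i, j = np.unravel_index(np.argmax(m), m.shape)
        return (
            (positions.iloc[i]["chromosome"], float(positions.iloc[i]["pos_cM"])),
            (positions.iloc[j]["chromosome"], float(positions.iloc[j]["pos_cM"])),
        )

    return PairScanResult(
        positions=positions,
        lod_full=lod_f,
        lod_add=lod_a,
        lod_int=lod_i,
        peak_full=argpeak(lod_f),
        peak_int=argpeak(lod_i),
    )


# ---------------------------------------------------------------------------
# Multiple-QTL fit


def _locus_index(grid: PositionGrid, chrom, cm: float) -> int:
    idx = grid.chrom_slice(chrom)
    if len(idx) == 0:
        raise ValueError(f"locus chromosome {chrom!r} not in grid")
    pos = grid.positions["pos_cM"].to_numpy()[idx]
    return int(idx[np.argmin(np.abs(pos - cm))])


def fit_multiple_qtl(grid: PositionGrid, phenotype, loci, interactions=()) -> MultiQtlFit:
    """Joint multiple-QTL regression with drop-one variance decomposition.

    ``loci``: list of (chromosome, cM).  ``interactions``: pairs of locus
    indices into that list; interaction terms are the products of the two
    loci's genetic columns.  Reports the full-model percentage of phenotypic
    variance explained, and per term the drop-one variance share with its
    F statistic (dropping a locus also drops interactions containing it).
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    G = grid.genetic_design()
    locus_idx = [_locus_index(grid, c, p) for c, p in loci]
    main = {t: G[j] for t, j in enumerate(locus_idx)}
    inter = {}
    for a, b in interactions:
        gi, gj = main[a], main[b]
        inter[(a, b)] = np.einsum("nk,nl->nkl", gi, gj).reshape(n, -1)

    def design(drop_locus=None, drop_inter=None):
        cols = [np.ones((n, 1))]
        for t in main:
            if t != drop_locus:
                cols.append(main[t])
        for pair, cols_i in inter.items():
            if drop_locus in pair or pair == drop_inter:
                continue
            cols.append(cols_i)
        return np.concatenate(cols, axis=1)

    X_full = design()
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient multiple-QTL design ({rank} < {X_full.shape[1]}): "
            f"aliased terms among loci {loci} and interactions {list(interactions)}"
        )
    rss_null = float(np.sum((y - y.mean()) ** 2))
    rss_full = max(_rss(X_full, y), 1e-12)
    pct_full = 100.0 * (1.0 - rss_full / rss_null)
    lod_full = 0.5 * n * math.log10(rss_null / rss_full)

    term_names, pct_terms, f_stats, p_values = [], [], [], []
    df_full = n - X_full.shape[1]
    for t, (c, p) in enumerate(loci):
        X_red = design(drop_locus=t)
        rss_red = _rss(X_red, y)
        df_diff = X_full.shape[1] - X_red.shape[1]
        f = ((rss_red - rss_full) / df_diff) / (rss_full / df_full)
        term_names.append(f"{c}@{p}")
        pct_terms.append(100.0 * (rss_red - rss_full) / rss_null)
        f_stats.append(float(f))
        p_values.append(float(stats.f.sf(f, df_diff, df_full)))
    for pair in inter:
        X_red = design(drop_inter=pair)
        rss_red = _rss(X_red, y)
        df_diff = X_full.shape[1] - X_red.shape[1]
        f = ((rss_red - rss_full) / df_diff) / (rss_full / df_full)
        a, b = pair
        term_names.append(f"{loci[a][0]}@{loci[a][1]} x {loci[b][0]}@{loci[b][1]}")
        pct_terms.append(100.0 * (rss_red - rss_full) / rss_null)
        f_stats.append(float(f))
        p_values.append(float(stats.f.sf(f, df_diff, df_full)))

    return MultiQtlFit(
        terms=term_names,
        pct_variance_full=pct_full,
        pct_variance_per_term=pct_terms,
        f_stats=f_stats,
        p_values=p_values,
        lod_full=lod_full,
        n=n,
    )
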