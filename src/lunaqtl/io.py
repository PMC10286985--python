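"""Format adapters, run configuration, provenance, and the pipeline driver.

File dialects: emergence CSV (see :mod:`lunaqtl.circstats`), genotype-matrix
TSV (see :mod:`lunaqtl.crossmap`), scan CSV + JSON sidecar, panel report CSV,
and xlsx import/export for genotype matrices and emergence sheets laid out
like deposited QTL-mapping supplementary workbooks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circstats, crossmap, phenotyping, qtlscan, empanel, synthdata

__all__ = [
    "RunConfig",
    "load_config",
    "run_pipeline",
    "write_scan",
    "write_panels",
    "export_genotype_xlsx",
    "import_supplementary_tables",
    "plot_lod",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; every stochastic stage has a seed."""

    out_dir: str = "lunaqtl_out"
    regime: str = "turbulence"  # turbulence (period 15) or moonlight (period 30)
    day1: int | None = 1
    bandwidth: float = 10.0
    reduce_lo: float = 0.3
    reduce_hi: float = 0.7
    step_cM: float = 1.0
    error_rate: float = 1e-4
    n_perm: int = 1000
    alpha: float = 0.05
    n_cofactors: int = 5
    window_cM: float = 10.0
    pair_step_cM: float = 2.5
    em_runs: int = 1000
    report_floor: float = 5.0
    seed: int = 1
    # inputs: either simulate, or paths to emergence CSVs + genotype TSV
    simulate: dict | None = None
    progeny_csv: str | None = None
    sensitive_csv: str | None = None
    insensitive_csv: str | None = None
    genotype_tsv: str | None = None
    cross_type: str = "F2"
    stages: list = field(default_factory=lambda: ["phenotype", "scan"])

    def validate(self) -> None:
        errors = []
        if self.regime not in ("turbulence", "moonlight"):
            errors.append("regime: must be 'turbulence' or 'moonlight'")
        if self.day1 is None:
            errors.append("day1: missing zeitgeber-log anchor")
        if not 0 <= self.reduce_lo < self.reduce_hi <= 1:
            errors.append("reduce_lo/reduce_hi: need 0 <= lo < hi <= 1")
        if self.simulate is None and self.genotype_tsv is None:
            errors.append("genotype_tsv: required unless 'simulate' is given")
        known = {"phenotype", "reduce", "scan", "cim", "scantwo", "fit", "empanel"}
        for s in self.stages:
            if s not in known:
                errors.append(f"stages: unknown stage {s!r}")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    @property
    def zeitgeber(self) -> phenotyping.ZeitgeberRegime:
        return phenotyping.TURBULENCE if self.regime == "turbulence" else phenotyping.MOONLIGHT


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _provenance(cfg: RunConfig, extra: dict | None = None) -> dict:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    prov = {
        "config_sha256": hashlib.sha256(payload).hexdigest()[:16],
        "seed": cfg.seed,
    }
    if extra:
        prov.update(extra)
    return prov


def write_scan(path_prefix: Path, scan: qtlscan.ScanResult, provenance: dict) -> None:
    scan.table.to_csv(f"{path_prefix}.csv", index=False)
    side = {
        "model": scan.model,
        "peak": [str(scan.peak_chromosome), scan.peak_cM],
        "max_lod": scan.max_lod,
        "threshold": scan.threshold,
        "interval": list(scan.interval) if scan.interval else None,
        **provenance,
    }
    Path(f"{path_prefix}.json").write_text(json.dumps(side, indent=2, default=str))


def write_panels(out_dir: Path, panels: empanel.PanelSet, individuals, provenance: dict) -> None:
    rows, matrix = [], {}
    for i, res in enumerate(panels.panels):
        pid = f"panel_{i:02d}"
        chrom, lo, hi = res.interval if res.interval else ("", np.nan, np.nan)
        rows.append(
            {
                "panel_id": pid,
                "convergence_pct": res.convergence_pct,
                "error_fraction": res.error_fraction,
                "max_lod": res.max_lod,
                "peak_chr": res.peak[0] if res.peak else "",
                "peak_cM": res.peak[1] if res.peak else np.nan,
                "interval_lo_cM": lo,
                "interval_hi_cM": hi,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "panels.csv", index=False)
    for i, res in enumerate(panels.panels):
        matrix[f"panel_{i:02d}"] = res.panel.astype(int)
    pd.DataFrame(matrix, index=list(individuals)).to_csv(out_dir / "panel_matrix.csv")
    meta = {
        "n_runs": panels.n_runs,
        "failed_runs": panels.failed_runs,
        "report_floor": panels.report_floor,
        **provenance,
    }
    (out_dir / "panels.json").write_text(json.dumps(meta, indent=2))


def plot_lod(scan: qtlscan.ScanResult, path) -> None:
    """Simple LOD profile figure, one panel per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(scan.table["chromosome"]))
    fig, axes = plt.subplots(1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, chrom in zip(axes, chroms):
        sub = scan.table[scan.table["chromosome"] == chrom]
        ax.plot(sub["pos_cM"], sub["lod"], lw=1.2)
        if scan.threshold is not None:
            ax.axhline(scan.threshold, ls="--", c="gray", lw=0.8)
        ax.set_title(str(chrom))
        ax.set_xlabel("cM")
    axes[0].set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pipeline driver


def run_pipeline(cfg: RunConfig) -> dict:
    """Phenotype -> reduce -> scan (+ optional cim/scantwo/fit/empanel).

    Returns a result bundle dict; every output file carries a provenance
    sidecar with the config hash and seeds.  Inputs are never mutated.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regime = cfg.zeitgeber
    bundle: dict = {}

    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        arch = synthdata.ArchitectureConfig(
            loci=[synthdata.Locus(*l) for l in sim_kwargs.pop("loci", [("chr2", 55.0)])]
        )
        n = sim_kwargs.pop("n", 300)
        cross_type = sim_kwargs.pop("cross_type", cfg.cross_type)
        sim = synthdata.simulate_cross(arch, cross_type, n, seed=cfg.seed, **sim_kwargs)
        progeny = sim.emergence
        sens_tbl = synthdata.simulate_strain_emergence(
            synthdata.SENSITIVE_DEFAULT, 300, cfg.seed + 1, family="sensitive"
        )
        insens_tbl = synthdata.simulate_strain_emergence(
            synthdata.INSENSITIVE_DEFAULT, 300, cfg.seed + 2, family="insensitive"
        )
        matrix = sim.matrix
        (out / "truth.json").write_text(json.dumps(sim.truth, indent=2))
        bundle["simulation"] = sim
    else:
        progeny = circstats.read_emergence_csv(cfg.progeny_csv)
        sens_tbl = circstats.read_emergence_csv(cfg.sensitive_csv)
        insens_tbl = circstats.read_emergence_csv(cfg.insensitive_csv)
        matrix = crossmap.read_genotype_tsv(cfg.genotype_tsv, cfg.cross_type)

    prov = _provenance(cfg)

    pheno, profile, shift = phenotyping.probability_phenotypes(
        progeny, sens_tbl, insens_tbl, regime, day1=cfg.day1, bandwidth=cfg.bandwidth
    )
    binary, n_excluded = phenotyping.reduce_dataset(
        pheno["p_insensitive"], cfg.reduce_lo, cfg.reduce_hi
    )
    pheno = pheno.copy()
    pheno["binary"] = binary
    pheno["excluded"] = np.isnan(binary)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    pd.DataFrame(
        {
            "day": np.arange(1, profile.period + 1),
            "f_sensitive": profile.f_sensitive,
            "f_insensitive": profile.f_insensitive,
            "p_insensitive": profile.posterior_insensitive,
        }
    ).to_csv(out / "profile.csv", index=False)
    ratio = phenotyping.estimate_ratio(pheno["p_insensitive"])
    (out / "phenotype.json").write_text(
        json.dumps(
            {
                "mixing_proportion": profile.mixing_proportion,
                "bandwidth": cfg.bandwidth,
                "phase_shift": shift,
                "ratio_sensitive_insensitive": list(ratio),
                "n_excluded": n_excluded,
                **prov,
            },
            indent=2,
        )
    )
    bundle.update(phenotypes=pheno, profile=profile, ratio=ratio)

    if not {"scan", "cim", "scantwo", "fit", "empanel"} & set(cfg.stages):
        return bundle

    # align phenotypes to genotyped individuals
    pheno_by_ind = pheno.set_index("individual") if "individual" in pheno.columns else pheno
    inds = [i for i in matrix.individuals if i in pheno_by_ind.index]
    if not inds:
        raise ValueError("no overlap between genotyped and phenotyped individuals")
    if set(matrix.individuals) - set(inds):
        matrix = crossmap.GenotypeMatrix(
            cross_type=matrix.cross_type,
            markers=matrix.markers,
            calls=matrix.calls.loc[inds],
            parent_calls=matrix.parent_calls,
        )
    y = pheno_by_ind.loc[inds, "p_insensitive"].to_numpy(dtype=float)

    gmap = matrix.markers
    if "position_cM" not in gmap.table.columns:
        gmap = crossmap.build_genetic_map(matrix)
    grid = qtlscan.genotype_probabilities(matrix, gmap, step_cM=cfg.step_cM, error_rate=cfg.error_rate)

    if "scan" in cfg.stages:
        scan = qtlscan.scan_single(grid, y, model="quantitative")
        scan.threshold = qtlscan.permutation_threshold(
            grid, y, "quantitative", n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed
        )
        lo, hi = qtlscan.bayes_interval(scan, scan.peak_chromosome)
        scan.interval = (scan.peak_chromosome, lo, hi)
        write_scan(out / "scan", scan, prov)
        bundle["scan"] = scan
    if "cim" in cfg.stages:
        cim = qtlscan.cim_scan(grid, y, n_cofactors=cfg.n_cofactors, window_cM=cfg.window_cM)
        write_scan(out / "cim", cim, prov)
        bundle["cim"] = cim
    if "scantwo" in cfg.stages:
        pairs = qtlscan.scan_pairs(grid, y, step_cM=cfg.pair_step_cM)
        np.savetxt(out / "scantwo_lodf.csv", pairs.lod_full, delimiter=",")
        np.savetxt(out / "scantwo_lodi.csv", pairs.lod_int, delimiter=",")
        bundle["scantwo"] = pairs
    if "fit" in cfg.stages:
        scan = bundle.get("scan") or qtlscan.scan_single(grid, y)
        fit = qtlscan.fit_multiple_qtl(grid, y, [(scan.peak_chromosome, scan.peak_cM)])
        (out / "fitqtl.json").write_text(
            json.dumps(
                {
                    "terms": fit.terms,
                    "pct_variance_full": fit.pct_variance_full,
                    "pct_variance_per_term": fit.pct_variance_per_term,
                    "f_stats": fit.f_stats,
                    "p_values": fit.p_values,
                    **prov,
                },
                indent=2,
            )
        )
        bundle["fit"] = fit
    if "empanel" in cfg.stages:
        panels = empanel.optimize_panels(
            grid, y, n_runs=cfg.em_runs, seed=cfg.seed, report_floor=cfg.report_floor
        )
        write_panels(out, panels, inds, prov)
        bundle["panels"] = panels
    return bundle


# ---------------------------------------------------------------------------
# xlsx adapters
#
# Genotype sheet layout: header row "marker_id, chromosome, position_bp,
# [position_cM,] <individual ids...>"; one row per marker with AA/AB/BB/-
# calls.  Emergence sheet layout: header "family, individual,
# experimental_day[, sex][, count]".  Anything else fails loudly.

_GENO_META = ["marker_id", "chromosome", "position_bp", "position_cM"]


def export_genotype_xlsx(path, matrix: crossmap.GenotypeMatrix) -> None:
    tbl = matrix.markers.table.set_index("marker_id")
    df = pd.concat([tbl, matrix.calls.T], axis=1)
    df.index.name = "marker_id"
    df.reset_index().to_excel(path, index=False, sheet_name="genotypes")


def import_supplementary_tables(path, kind: str, cross_type: str = "F2"):
    """Import a genotype-matrix or emergence workbook sheet.

    ``kind``: 'genotypes' -> GenotypeMatrix; 'emergence' -> emergence table.
    Unparseable genotype cells are set missing with a warning carrying their
    sheet/row/column coordinates.
    """
    if kind == "emergence":
        df = pd.read_excel(path)
        need = {"family", "individual", "experimental_day"}
        if not need <= set(df.columns):
            raise ValueError(
                f"unrecognized emergence sheet columns {list(df.columns)}; "
                f"recognized layout requires {sorted(need)}"
            )
        if "count" not in df.columns:
            df["count"] = 1
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        return df
    if kind != "genotypes":
        raise ValueError("kind must be 'genotypes' or 'emergence'")
    df = pd.read_excel(path)
    if not {"marker_id", "chromosome", "position_bp"} <= set(df.columns):
        raise ValueError(
            f"unrecognized genotype sheet columns {list(df.columns)}; recognized "
            "layout: marker_id, chromosome, position_bp[, position_cM], individuals..."
        )
    meta_cols = [c for c in _GENO_META if c in df.columns]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    calls = df[ind_cols].astype(object)
    valid = {"AA", "AB", "BB", crossmap.MISSING}
    n_bad = 0
    for col in ind_cols:
        for row in calls.index:
            v = calls.at[row, col]
            if pd.isna(v):
                calls.at[row, col] = crossmap.MISSING
            elif v not in valid:
                log.warning("malformed genotype cell at row %d column %r: %r -> missing", row + 2, col, v)
                calls.at[row, col] = crossmap.MISSING
                n_bad += 1
    markers = crossmap.MarkerMap(df[meta_cols])
    calls.index = df["marker_id"]
    matrix = crossmap.GenotypeMatrix(
        cross_type=cross_type, markers=markers, calls=calls.T, parent_calls=None
    )
    log.info(
        "imported %d markers x %d individuals (%d malformed cells)",
        len(markers.table),
        len(matrix.individuals),
        n_bad,
    )
    return matrix
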