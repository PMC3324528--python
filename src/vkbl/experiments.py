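"""Config-driven experiment runner for the desk-scale parameter scans.

System size is varied two ways — gene copy number and the transcription
multiplier transMF — and each (delta_R, size, replicate) cell is simulated,
burst-detected and summarised into IBI and regularity tables.  Seeds are a
deterministic function of the cell's physical coordinates (not of grid
position), so the transMF = 1 column of a transcription scan reproduces the
N = 1 cell of a copy scan bit for bit under the same base seed.

Run lengths adapt per cell: a run is extended (by deterministically
re-running the same seed at a longer horizon) until it holds at least ``min_ibis``
intervals or hits the hard cap, in which case the cell is flagged censored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bursts import analyze_trajectory, replicate_summary
from .circuit import default_parameters
from .firstpassage import FitResult, fit_ibi_curve
from .ode import bifurcation_diagram
from .ssa import MAX_SEED, simulate_ssa

__all__ = ["ExperimentConfig", "cell_seed", "run_cell", "run_copy_scan",
           "run_transmf_scan", "run_fpt_fit", "aggregate", "run_all",
           "matched_product_pairs"]


@dataclass(frozen=True)
class ExperimentConfig:
    kind: str = "copy_scan"   # copy_scan | transmf_scan | bifurcation | fpt_fit | single_run
    delta_R_values: tuple[float, ...] = (0.06, 0.08, 0.09, 0.12)
    gene_copies: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 48)
    transmf_values: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    replicates: int = 10
    base_seed: int = 12345
    dt: float = 0.05
    theta_on_frac: float = 0.2
    theta_off_frac: float = 0.05
    min_ibis: int = 30        # extend runs until this many intervals
    t_chunk: float = 1500.0   # initial horizon, hours
    t_cap: float = 6000.0     # censoring cap, hours
    outdir: str = "results"
    # fpt_fit specifics: a single sub-onset delta_R and its own replicate count
    fpt_delta_R: float = 0.06
    fpt_replicates: int = 4

    def __post_init__(self) -> None:
        if self.replicates < 1 or not self.delta_R_values or not self.gene_copies:
            raise ValueError("grids must be non-empty and replicates >= 1")
        if not (0 <= self.base_seed < MAX_SEED):
            raise ValueError("base_seed must be in [0, 2^31)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("delta_R_values", "gene_copies", "transmf_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def cell_seed(base_seed: int, delta_R: float, gene_copy: int,
              transMF: float, replicate: int) -> int:
    """Deterministic seed from the physical cell coordinates.

    Hashing the values (rather than grid indices) makes seeds independent of
    how a scan's grids are ordered or nested.
    """
    tag = f"{delta_R:.10g}|{gene_copy}|{transMF:.10g}".encode()
    return (base_seed + (zlib.crc32(tag) % 2**20) * 1024 + replicate) % MAX_SEED


def run_cell(cfg: ExperimentConfig, delta_R: float, gene_copy: int,
             transMF: float, replicate: int) -> dict:
    """Simulate one replicate, adaptively extending the horizon, and return
    its IBI/regularity record.  Cells with too few bursts are reported with
    NaN statistics rather than fabricated values."""
    params = default_parameters(delta_R, gene_copy=gene_copy, transMF=transMF)
    net_seed = cell_seed(cfg.base_seed, delta_R, gene_copy, transMF, replicate)
    from .circuit import build_network
    network = build_network(params)
    t_end = cfg.t_chunk
    result = None
    censored = False
    while True:
        traj = simulate_ssa(network, t_end, net_seed, dt=cfg.dt)
        try:
            mx = float(traj.series("R").max())
            result = analyze_trajectory(traj, cfg.theta_on_frac * mx,
                                        cfg.theta_off_frac * mx)
        except ValueError:
            result = None
        n = result.n_ibis if result is not None else 0
        if n >= cfg.min_ibis or t_end >= cfg.t_cap:
            censored = n < cfg.min_ibis
            break
        t_end = min(2 * t_end, cfg.t_cap)
    rec = {"delta_R": delta_R, "gene_copy": gene_copy, "transMF": transMF,
           "replicate": replicate, "seed": net_seed, "t_end": t_end,
           "censored": censored}
    if result is None:
        rec.update(n_ibi=0, mean_ibi_h=np.nan, sd_ibi_h=np.nan,
                   regularity=np.nan)
    else:
        rec.update(n_ibi=result.n_ibis, mean_ibi_h=result.mean_ibi,
                   sd_ibi_h=result.sd_ibi, regularity=result.regularity)
    return rec


def _scan(cfg: ExperimentConfig, cells: Sequence[tuple[float, int, float]],
          outdir: Path | None = None) -> pd.DataFrame:
    """Run a list of (delta_R, N, transMF) cells × replicates, resumable per
    cell when an output directory is given."""
    frames = []
    for delta_R, N, tmf in cells:
        tag = f"dR{delta_R:g}_N{N}_t{tmf:g}"
        cell_file = None
        if outdir is not None:
            cell_file = outdir / "cells" / f"{tag}.csv"
            if cell_file.exists():
                frames.append(pd.read_csv(cell_file))
                continue
        recs = [run_cell(cfg, delta_R, N, tmf, r)
                for r in range(cfg.replicates)]
        df = pd.DataFrame(recs)
        if cell_file is not None:
            cell_file.parent.mkdir(parents=True, exist_ok=True)
            df.to_csv(cell_file, index=False)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_copy_scan(cfg: ExperimentConfig,
                  outdir: Path | None = None) -> pd.DataFrame:
    """IBI and regularity versus gene copy number for each delta_R."""
    cells = [(d, N, 1.0) for d in cfg.delta_R_values for N in cfg.gene_copies]
    return _scan(cfg, cells, outdir)


def run_transmf_scan(cfg: ExperimentConfig, gene_copy: int = 1,
                     outdir: Path | None = None) -> pd.DataFrame:
    """Regularity versus transMF at fixed gene copy number (default 1)."""
    cells = [(d, gene_copy, t) for d in cfg.delta_R_values
             for t in cfg.transmf_values]
    return _scan(cfg, cells, outdir)


def matched_product_pairs(products: Sequence[float] = (2.0, 3.0)
                          ) -> list[tuple[int, float]]:
    """(gene_copy, transMF) combinations with equal products N × transMF,
    for comparing the two ways of growing the system."""
    pairs = []
    for prod in products:
        for N in (1, 2, 3):
            t = prod / N
            if t > 0 and (N, t) not in pairs:
                pairs.append((N, t))
    return pairs


def aggregate(df: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate mean ± SE of regularity and mean IBI per cell."""
    rows = []
    for (d, N, t), g in df.groupby(["delta_R", "gene_copy", "transMF"]):
        reg = g["regularity"].dropna().to_numpy()
        ibi = g["mean_ibi_h"].dropna().to_numpy()
        row = {"delta_R": d, "gene_copy": N, "transMF": t,
               "n_replicates": len(g), "n_missing": int(g["regularity"].isna().sum())}
        for name, vals in (("regularity", reg), ("mean_ibi_h", ibi)):
            if vals.size:
                mean, se = replicate_summary(vals)
                row[name], row[f"{name}_se"] = mean, se
            else:
                row[name] = row[f"{name}_se"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_fpt_fit(cfg: ExperimentConfig,
                outdir: Path | None = None) -> tuple[pd.DataFrame, FitResult]:
    """Measure IBI(N) below the oscillation onset and fit the first-passage
    curve to the replicate-averaged means."""
    sub = dataclasses.replace(cfg, replicates=cfg.fpt_replicates)
    cells = [(cfg.fpt_delta_R, N, 1.0) for N in cfg.gene_copies]
    df = _scan(sub, cells, outdir)
    agg = aggregate(df).dropna(subset=["mean_ibi_h"])
    fit = fit_ibi_curve(agg["gene_copy"].to_numpy(float),
                        agg["mean_ibi_h"].to_numpy())
    return df, fit


def run_all(cfg: ExperimentConfig) -> dict:
    """Dispatch one experiment kind, write its tables and a manifest.

    Stochastic outputs are bitwise-reproducible for a fixed config; a partial
    earlier run leaves completed per-cell files in place and they are reused.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(name)

    if cfg.kind == "copy_scan":
        df = run_copy_scan(cfg, outdir)
        save(df, "regularity.csv")
        save(aggregate(df), "regularity_aggregated.csv")
    elif cfg.kind == "transmf_scan":
        df = run_transmf_scan(cfg, outdir=outdir)
        save(df, "regularity_transmf.csv")
        save(aggregate(df), "regularity_transmf_aggregated.csv")
    elif cfg.kind == "bifurcation":
        params = default_parameters(cfg.delta_R_values[0])
        grid = np.linspace(min(cfg.delta_R_values), max(cfg.delta_R_values), 31)
        scan = bifurcation_diagram(params, grid)
        save(pd.DataFrame({"delta_R": scan.delta_R, "R_max": scan.R_max,
                           "R_min": scan.R_min, "max_re_eig": scan.max_re_eig}),
             "bifurcation.csv")
    elif cfg.kind == "fpt_fit":
        df, fit = run_fpt_fit(cfg, outdir)
        save(df, "fpt_ibis.csv")
        p = fit.params
        (outdir / "fpt_fit.json").write_text(json.dumps(
            {"T_B": p.T_B, "T_0": p.T_0, "a": p.a, "rss": fit.rss,
             "residuals": fit.residuals.tolist()}, indent=2))
        written.append("fpt_fit.json")
    elif cfg.kind == "single_run":
        from .circuit import build_network
        params = default_parameters(cfg.delta_R_values[0],
                                    gene_copy=cfg.gene_copies[0])
        traj = simulate_ssa(build_network(params), cfg.t_chunk,
                            cfg.base_seed, dt=cfg.dt)
        traj.meta["params"] = params
        traj.to_tsv(outdir / "trace.tsv")
        written.append("trace.tsv")
    else:
        raise ValueError(f"unknown experiment kind {cfg.kind!r}")

    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
                "outputs": written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
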