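"""Config-driven orchestration: simulate -> preprocess -> fit -> decode -> report.

One YAML config drives every stage; the shipped ``paper2018`` profile holds
the study-protocol defaults (20 km/h speed filter, 12-h gap, 24-h minimum
span, 10-m / 20-s dive definition, 6-h interval, 2 chains of 30,000
iterations with 28,000 burn-in thinned by 4).  Every command logs its
resolved configuration and a content hash of its inputs to stderr, so the
provenance chain is reconstructible from the logs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcmc import RHAT_THRESHOLD, McmcConfig, PosteriorDraws, run_mcmc
from .model import (ArgosErrorTable, ModelParameters, ParameterError,
                    default_error_table)
from .preprocess import (RegularTrack, preprocess as run_preprocessing,
                         project_to_plane, read_dives, read_fixes)
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .summaries import (decode, deep_dive_count, depth_distribution_summary,
                        state_time_proportions, temporal_frequency)
from .tracks import TrackData

log = logging.getLogger("nestmove")


class ConvergenceError(RuntimeError):
    """Raised in strict mode when any parameter's Gelman-Rubin >= 1.1."""


@dataclass
class FilterSettings:
    max_speed_kmh: float = 20.0
    max_gap_h: float = 12.0
    min_span_h: float = 24.0
    min_dive_depth_m: float = 10.0
    min_dive_duration_s: float = 20.0
    interval_hours: float = 6.0


@dataclass
class PipelineConfig:
    out_dir: str = "nestmove_out"
    fixes_path: str | None = None
    dives_path: str | None = None
    projection_center: tuple[float, float] | None = None
    land_mask_geojson: str | None = None
    exclusion_windows: dict = field(default_factory=dict)
    error_table_path: str | None = None
    filters: FilterSettings = field(default_factory=FilterSettings)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    strict: bool = True
    plots: bool = True
    deep_dive_threshold_m: float = 400.0
    uncertainty_draws: int = 50

    def error_table(self) -> ArgosErrorTable:
        if self.error_table_path:
            return ArgosErrorTable.from_yaml(Path(self.error_table_path).read_text())
        return default_error_table()

    def resolved(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "fixes_path": self.fixes_path,
            "dives_path": self.dives_path,
            "projection_center": self.projection_center,
            "land_mask_geojson": self.land_mask_geojson,
            "exclusion_windows": self.exclusion_windows,
            "error_table_path": self.error_table_path,
            "filters": dataclasses.asdict(self.filters),
            "simulation": self.simulation.as_dict(),
            "mcmc": {k: v for k, v in vars(self.mcmc).items()},
            "strict": self.strict,
            "plots": self.plots,
            "deep_dive_threshold_m": self.deep_dive_threshold_m,
            "uncertainty_draws": self.uncertainty_draws,
        }
        return d


def load_config(path: str | Path | None = None, profile: str = "paper2018",
                seed: int | None = None, out: str | None = None
                ) -> PipelineConfig:
    """Build a config from the named profile, an optional YAML file and
    command-line overrides (later sources win)."""
    if profile != "paper2018":
        raise ParameterError(f"unknown profile {profile!r}")
    cfg = PipelineConfig()
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("out_dir", "fixes_path", "dives_path", "land_mask_geojson",
                    "error_table_path", "strict", "plots",
                    "deep_dive_threshold_m", "uncertainty_draws"):
            if key in payload:
                setattr(cfg, key, payload[key])
        if "projection_center" in payload and payload["projection_center"]:
            cfg.projection_center = tuple(payload["projection_center"])
        if "exclusion_windows" in payload:
            cfg.exclusion_windows = payload["exclusion_windows"] or {}
        for key, val in (payload.get("filters") or {}).items():
            setattr(cfg.filters, key, val)
        sim = payload.get("simulation") or {}
        if "true_params" in sim:
            cfg.simulation.true_params = ModelParameters(
                **{k: np.asarray(v, float) for k, v in sim.pop("true_params").items()})
        for key, val in sim.items():
            setattr(cfg.simulation, key, val)
        for key, val in (payload.get("mcmc") or {}).items():
            setattr(cfg.mcmc, key, val)
    if seed is not None:
        cfg.simulation.seed = int(seed)
        cfg.mcmc.seed = int(seed)
    if out is not None:
        cfg.out_dir = out
    return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log_stage(stage: str, **kv) -> None:
    fields = " ".join(f"{k}={v}" for k, v in kv.items())
    log.info("stage=%s %s", stage, fields)


def _log_inputs(stage: str, *paths: Path) -> None:
    for p in paths:
        if p is not None and Path(p).exists():
            _log_stage(stage, event="input", path=str(p), sha256=_hash_file(Path(p)))


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def cmd_simulate(cfg: PipelineConfig) -> dict:
    """Generate a synthetic dataset and write it under ``out_dir/data``."""
    _log_stage("simulate", event="config", **{"seed": cfg.simulation.seed,
               "n_animals": cfg.simulation.n_animals})
    cfg.simulation.error_table = cfg.error_table()
    ds = simulate_dataset(cfg.simulation)
    paths = write_dataset(ds, Path(cfg.out_dir) / "data")
    _log_stage("simulate", event="written", n_fixes=len(ds.fixes),
               n_dives=len(ds.dives))
    return {k: str(v) for k, v in paths.items()}


def _land_mask(cfg: PipelineConfig):
    if not cfg.land_mask_geojson:
        return None
    import shapely.geometry as geom

    payload = json.loads(Path(cfg.land_mask_geojson).read_text())
    shapes = [geom.shape(f["geometry"]) for f in payload.get("features", [payload])]

    def mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pts = [geom.Point(xi, yi) for xi, yi in zip(x, y)]
        return np.array([any(s.contains(p) for s in shapes) for p in pts])

    return mask


def cmd_preprocess(cfg: PipelineConfig) -> dict:
    """Run the filtering chain and write regularized tracks + a report."""
    data_dir = Path(cfg.out_dir) / "data"
    fixes_path = Path(cfg.fixes_path or data_dir / "fixes.csv")
    dives_path = Path(cfg.dives_path or data_dir / "dives.csv")
    _log_inputs("preprocess", fixes_path, dives_path)
    fixes, rep_ts_f = read_fixes(fixes_path)
    dives, rep_ts_d = read_dives(dives_path)
    if "lon" in fixes.columns and "x_km" not in fixes.columns:
        fixes = project_to_plane(fixes, center=cfg.projection_center)
    windows = {a: [(w[0], w[1]) for w in ws]
               for a, ws in (cfg.exclusion_windows or {}).items()}
    f = cfg.filters
    tracks, report = run_preprocessing(
        fixes, dives, land_mask=_land_mask(cfg), exclusion_windows=windows,
        max_speed=f.max_speed_kmh, max_gap=f.max_gap_h, min_span=f.min_span_h,
        min_depth=f.min_dive_depth_m, min_duration=f.min_dive_duration_s,
        interval_hours=f.interval_hours)
    report["read"] = {"fixes": rep_ts_f, "dives": rep_ts_d}
    out = Path(cfg.out_dir) / "preprocessed"
    write_regular_tracks(tracks, out)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _log_stage("preprocess", event="done", n_tracks=len(tracks),
               n_fixes=sum(t.fix_x.size for t in tracks),
               n_dives=sum(t.dive_depth.size for t in tracks))
    return report


def write_regular_tracks(tracks: list[RegularTrack], outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trows, frows, drows = [], [], []
    for t in tracks:
        trows.append({"animal": t.animal, "track": t.track_id,
                      "t0": str(np.datetime64(t.t0, "s")),
                      "n_intervals": t.n_intervals,
                      "interval_hours": t.interval_hours})
        frows.append(pd.DataFrame({
            "animal": t.animal, "track": t.track_id,
            "interval": t.fix_interval, "j": t.fix_j,
            "x_km": t.fix_x, "y_km": t.fix_y, "argos_class": t.fix_class}))
        drows.append(pd.DataFrame({
            "animal": t.animal, "track": t.track_id,
            "interval": t.dive_interval, "order": t.dive_order,
            "timestamp": [str(x) for x in t.dive_time],
            "depth_m": t.dive_depth, "duration_s": t.dive_duration}))
    pd.DataFrame(trows).to_csv(outdir / "tracks.csv", index=False)
    pd.concat(frows, ignore_index=True).to_csv(outdir / "reg_fixes.csv", index=False)
    pd.concat(drows, ignore_index=True).to_csv(outdir / "reg_dives.csv", index=False)


def load_regular_tracks(outdir: Path) -> list[RegularTrack]:
    outdir = Path(outdir)
    meta = pd.read_csv(outdir / "tracks.csv", dtype={"animal": str})
    fixes = pd.read_csv(outdir / "reg_fixes.csv",
                        dtype={"animal": str, "argos_class": str})
    dives = pd.read_csv(outdir / "reg_dives.csv", dtype={"animal": str})
    out = []
    for _, row in meta.iterrows():
        fsel = fixes[(fixes["animal"] == row["animal"])
                     & (fixes["track"] == row["track"])]
        dsel = dives[(dives["animal"] == row["animal"])
                     & (dives["track"] == row["track"])]
        out.append(RegularTrack(
            animal=row["animal"], track_id=int(row["track"]),
            t0=np.datetime64(row["t0"], "s"),
            n_intervals=int(row["n_intervals"]),
            fix_interval=fsel["interval"].to_numpy(np.int64),
            fix_j=fsel["j"].to_numpy(float),
            fix_x=fsel["x_km"].to_numpy(float), fix_y=fsel["y_km"].to_numpy(float),
            fix_class=fsel["argos_class"].to_numpy(str),
            dive_interval=dsel["interval"].to_numpy(np.int64),
            dive_order=dsel["order"].to_numpy(np.int64),
            dive_depth=dsel["depth_m"].to_numpy(float),
            dive_duration=dsel["duration_s"].to_numpy(float),
            dive_time=dsel["timestamp"].to_numpy("datetime64[s]"),
            interval_hours=float(row["interval_hours"]),
        ))
    return out


def cmd_fit(cfg: PipelineConfig, strict: bool | None = None) -> PosteriorDraws:
    """Fit the nested model by MCMC; write draws, an rhat table and the
    acceptance log.  In strict mode a fit with any Gelman-Rubin >= 1.1
    raises :class:`ConvergenceError`."""
    strict = cfg.strict if strict is None else strict
    pre = Path(cfg.out_dir) / "preprocessed"
    if not (pre / "tracks.csv").exists():
        raise FileNotFoundError(f"no preprocessed tracks under {pre}")
    _log_inputs("fit", pre / "tracks.csv", pre / "reg_fixes.csv",
                pre / "reg_dives.csv")
    regs = load_regular_tracks(pre)
    if not regs:
        raise ParameterError("empty track set")
    table = cfg.error_table()
    tracks = [TrackData.from_regular(r, table) for r in regs]
    _log_stage("fit", event="start", n_tracks=len(tracks),
               n_iter=cfg.mcmc.n_iter, n_chains=cfg.mcmc.n_chains)
    draws = run_mcmc(tracks, cfg.mcmc)
    ddir = Path(cfg.out_dir) / "draws"
    draws.save(ddir)
    rhat = draws.rhat_table()
    rhat.to_csv(ddir / "rhat.csv", index=False)
    (ddir / "diagnostics.json").write_text(json.dumps({
        "max_rhat": draws.max_rhat(),
        "acceptance": draws.acceptance,
        "n_draws": draws.n_draws,
    }, indent=2, sort_keys=True))
    _log_stage("fit", event="done", max_rhat=f"{draws.max_rhat():.4f}")
    if strict and draws.max_rhat() >= RHAT_THRESHOLD:
        raise ConvergenceError(
            f"max Gelman-Rubin {draws.max_rhat():.3f} >= {RHAT_THRESHOLD}")
    return draws


def cmd_decode(cfg: PipelineConfig) -> dict:
    """Decode modal states from saved draws and write the label tables."""
    ddir = Path(cfg.out_dir) / "draws"
    if not (ddir / "meta.json").exists():
        raise FileNotFoundError(f"no draws under {ddir}")
    draws = PosteriorDraws.load(ddir)
    decoded = decode(draws)
    out = Path(cfg.out_dir) / "decoded"
    out.mkdir(parents=True, exist_ok=True)
    decoded.intervals.to_csv(out / "intervals.csv", index=False)
    decoded.dives.to_csv(out / "dives.csv", index=False)
    _log_stage("decode", event="done", n_intervals=len(decoded.intervals),
               n_dives=len(decoded.dives))
    return {"intervals": str(out / "intervals.csv"),
            "dives": str(out / "dives.csv")}


def cmd_report(cfg: PipelineConfig) -> dict:
    """Run decoding and all behavioral summaries; write tables, a JSON
    report and (optionally) plots."""
    ddir = Path(cfg.out_dir) / "draws"
    if not (ddir / "meta.json").exists():
        raise FileNotFoundError(f"no draws under {ddir}")
    draws = PosteriorDraws.load(ddir)
    decoded = decode(draws)
    out = Path(cfg.out_dir) / "report"
    out.mkdir(parents=True, exist_ok=True)
    per_ind, summary = state_time_proportions(decoded)
    depth = depth_distribution_summary(decoded, draws)
    monthly = temporal_frequency(decoded, draws, "month", cfg.uncertainty_draws)
    hourly = temporal_frequency(decoded, draws, "hour", cfg.uncertainty_draws)
    deep = deep_dive_count(decoded, cfg.deep_dive_threshold_m)
    per_ind.to_csv(out / "proportions_by_individual.csv", index=False)
    summary.to_csv(out / "proportions_summary.csv", index=False)
    depth.to_csv(out / "depth_summary.csv", index=False)
    monthly.to_csv(out / "frequency_monthly.csv", index=False)
    hourly.to_csv(out / "frequency_hourly.csv", index=False)
    report = {
        "proportions": summary.to_dict(orient="records"),
        "depth": depth.to_dict(orient="records"),
        "deep_dives": deep,
        "max_rhat": draws.max_rhat(),
        "n_draws": draws.n_draws,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if cfg.plots:
        _write_plots(decoded, monthly, hourly, out)
    _log_stage("report", event="done", out=str(out))
    return report


def _write_plots(decoded, monthly: pd.DataFrame, hourly: pd.DataFrame,
                 out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for b in ("traveling", "foraging", "resting"):
        depths = decoded.dives.loc[decoded.dives["behavior"] == b, "depth_m"]
        if len(depths):
            ax.hist(depths, bins=40, alpha=0.5, label=b, density=True)
    ax.set_xlabel("maximum dive depth (m)")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(out / "depth_distributions.png", dpi=120)
    plt.close(fig)

    for name, table, xlab in (("frequency_monthly", monthly, "month"),
                              ("frequency_hourly", hourly, "hour (UTC)")):
        fig, ax = plt.subplots(figsize=(6, 4))
        for b in ("foraging", "resting"):
            sub = table[(table["behavior"] == b) & (table["n_dives"] > 0)]
            ax.errorbar(sub["bin"], sub["frequency"],
                        yerr=[sub["frequency"] - sub["band_low"],
                              sub["band_high"] - sub["frequency"]],
                        marker="o", capsize=2, label=b)
        ax.set_xlabel(xlab)
        ax.set_ylabel("behavior frequency")
        ax.set_ylim(0, 1)
        ax.legend()
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
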