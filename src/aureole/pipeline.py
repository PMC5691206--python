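"""End-to-end orchestration: simulate -> render -> measure -> fit -> report.

Stages communicate exclusively through files in the output directory (CSV
tables, TIFF frames, YAML ground truth), so any stage can be re-run or
audited in isolation; a manifest records the seed, a hash of the resolved
configuration, and the SHA-256 of every artifact, making end-to-end runs
reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, imaging, synth
from .model import aureole_width, critical_radius
from .presets import PRESETS, Preset, load_preset_params, preset_names

__all__ = [
    "PipelineConfig",
    "DependencyError",
    "load_preset",
    "run_pipeline",
    "STAGES",
]

logger = logging.getLogger("aureole")

STAGES = ("simulate", "render", "measure", "fit", "report")

#: frames are rendered at these times, matching the published micrograph grid
RENDER_HOURS = (0.0, 5.0, 10.0, 15.0)


class DependencyError(RuntimeError):
    """A stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``phi_S = None`` selects the highest coverage level of the preset.
    Unknown keys are rejected on load; the config round-trips losslessly
    through YAML.
    """

    preset: str = "SiO2Carbo1000"
    phi_S: float | None = None
    n_aggregates: int = 5
    seed: int = 0
    outdir: str = "aureole_out"
    stages: tuple = STAGES
    duration_s: float = 54000.0
    dt_s: float = 600.0
    area_noise: float = 0.05
    R0_um: float = 75.0
    pixel_size_um: float = 2.0
    make_zstack: bool = False

    def __post_init__(self) -> None:
        load_preset_params(self.preset)  # fail fast on unknown preset
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
        self.stages = tuple(self.stages)
        if self.phi_S is None:
            self.phi_S = max(load_preset_params(self.preset).phi_S_levels)

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()

    def sim_config(self) -> synth.SimConfig:
        return synth.SimConfig(
            preset=self.preset,
            phi_S=self.phi_S,
            R0_um=self.R0_um,
            duration_s=self.duration_s,
            dt_s=self.dt_s,
            area_noise=self.area_noise,
            seed=self.seed,
        )


def load_preset(name: str) -> PipelineConfig:
    """Fully-populated pipeline config for a named particle preset."""
    try:
        load_preset_params(name)
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
        ) from None
    return PipelineConfig(preset=name)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise DependencyError(f"stage {stage!r} needs missing artifact {path}")
    return path


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    sim = cfg.sim_config()
    records = synth.make_ensemble(sim, cfg.n_aggregates)
    rows = []
    truth = {"V_star_true_um_s": [], "seed": cfg.seed}
    for i, rec in enumerate(records):
        truth["V_star_true_um_s"].append(float(rec.V_star_true))
        for t, A in zip(rec.t_s, rec.A_um2):
            rows.append({"aggregate": i, "t_s": t, "A_um2": A, "R0_um": rec.R0_um})
    traj = pd.DataFrame(rows)
    traj.to_csv(out / "trajectories.csv", index=False)

    history = synth.simulate_front_uptake(sim)
    front = pd.DataFrame(
        {
            "t_s": history.t_s,
            "R_um": history.R_um,
            "Delta_um": history.delta_um,
            "internalized": [sum(s.internalized) for s in history.states],
            "adsorbed": [sum(s.adsorbed) for s in history.states],
            "substrate_remaining": [s.substrate_remaining for s in history.states],
            "unclaimed": [s.unclaimed for s in history.states],
        }
    )
    front.to_csv(out / "front.csv", index=False)
    truth["n_total_particles"] = history.n_total
    truth["conservation_ok"] = bool(history.conservation_ok())
    truth["phi_S"] = float(cfg.phi_S)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh)
    return [out / "trajectories.csv", out / "front.csv", out / "truth.yaml"]


def _stage_render(cfg: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "front.csv", "render")
    sim = cfg.sim_config()
    history = synth.simulate_front_uptake(sim)
    optics = synth.OpticsConfig(pixel_size_um=cfg.pixel_size_um)
    # shared field of view sized for the last frame, so the series is comparable
    last = history.final
    optics.fov_um = 2.3 * (last.R_um + last.delta_um)
    paths = []
    for hours in RENDER_HOURS:
        idx = int(np.argmin(np.abs(history.t_s - hours * 3600.0)))
        frame = synth.render_micrograph(
            history.states[idx], optics, seed=cfg.seed, d_cell_um=sim.geometry.d_cell_um
        )
        path = out / f"frame_t{int(hours):02d}h.tif"
        synth.write_frame(frame, path)
        paths += [path, Path(str(path) + ".truth.yaml")]
    if cfg.make_zstack and sim.particle is not None and sim.uptake is not None:
        stack = synth.render_zstack(sim.geometry, sim.uptake, sim.particle, seed=cfg.seed)
        path = out / "zstack.tif"
        synth.write_zstack(stack, path)
        paths += [path, Path(str(path) + ".truth.yaml")]
    return paths


def _stage_measure(cfg: PipelineConfig, out: Path) -> list[Path]:
    frames = sorted(out.glob("frame_t*h.tif"))
    if not frames:
        raise DependencyError("stage 'measure' needs rendered frames (frame_t*h.tif)")
    rows = []
    for path in frames:
        frame = synth.read_frame(path)
        A = imaging.measure_film_area(frame)
        meas = imaging.measure_aureole_width(frame)
        phi_S = imaging.measure_surface_fraction(frame)
        rows.append(
            {
                "t_s": frame.ground_truth.get("t_s", math.nan),
                "A_um2": A,
                "R_um": meas.R_outer_um,
                "Delta_um": meas.delta_um if meas.found else 0.0,
                "phi_S": phi_S,
            }
        )
    table = pd.DataFrame(rows).sort_values("t_s")
    table.to_csv(out / "measurements.csv", index=False)
    paths = [out / "measurements.csv"]
    if (out / "zstack.tif").exists():
        stack = synth.read_zstack(out / "zstack.tif")
        beads, nucleus = imaging.zstack_volume_fractions(stack)
        with open(out / "zstack_fractions.yaml", "w") as fh:
            yaml.safe_dump({"bead_fraction": beads, "nucleus_fraction": nucleus}, fh)
        paths.append(out / "zstack_fractions.yaml")
    return paths


def _stage_fit(cfg: PipelineConfig, out: Path) -> list[Path]:
    traj_path = _require(out, "trajectories.csv", "fit")
    meas_path = _require(out, "measurements.csv", "fit")
    traj = pd.read_csv(traj_path)
    fits = []
    for agg, group in traj.groupby("aggregate"):
        rec = synth.SpreadingRecord(
            t_s=group["t_s"].to_numpy(),
            A_um2=group["A_um2"].to_numpy(),
            R0_um=float(group["R0_um"].iloc[0]),
            A0_um2=math.pi * float(group["R0_um"].iloc[0]) ** 2,
            V_star_true=math.nan,
        )
        res = fitting.fit_velocity(rec)
        fits.append(
            {
                "aggregate": agg,
                "V_star_um_s": res["V_star_um_s"],
                "V_star_se": res.se["V_star_um_s"],
                "D_um2_s": res["D_um2_s"],
                "n_points": res.n,
            }
        )
    fit_table = pd.DataFrame(fits)
    fit_table.to_csv(out / "fits.csv", index=False)

    meas = pd.read_csv(meas_path)
    final = meas.iloc[-1]
    preset = load_preset_params(cfg.preset)
    report_lines = [
        f"preset: {cfg.preset}  phi_S: {cfg.phi_S}  seed: {cfg.seed}",
        f"aggregates fitted: {len(fit_table)}",
        f"mean V*: {fit_table['V_star_um_s'].mean():.3e} um/s "
        f"(SD {fit_table['V_star_um_s'].std(ddof=1):.1e})",
        f"final frame: R = {final['R_um']:.1f} um, Delta = {final['Delta_um']:.1f} um, "
        f"Delta/R = {final['Delta_um'] / final['R_um']:.3f}",
        f"measured phi_S: {final['phi_S']:.3f}",
    ]
    if preset.particle is not None and preset.phi_is > 0:
        up = preset.uptake(cfg.phi_S)
        pred = aureole_width(final["R_um"], cfg.phi_S, up, preset.geometry, preset.particle)
        report_lines.append(
            f"conservation-model Delta at this R: {pred:.1f} um "
            f"(R_c = {critical_radius(cfg.phi_S, up, preset.geometry, preset.particle):.1f} um)"
        )
    (out / "fit_report.txt").write_text("\n".join(report_lines) + "\n")
    return [out / "fits.csv", out / "fit_report.txt"]


def _stage_report(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = fitting.build_table1(list(PRESETS.values()))
    table.to_csv(out / "table1.csv", index=False)
    paths = [out / "table1.csv"]

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    preset: Preset = load_preset_params(cfg.preset)
    if preset.particle is not None and preset.phi_is > 0:
        phis = np.linspace(0.01, max(preset.phi_S_levels), 200)
        ratios = []
        R_ref = 500.0  # supra-critical reference radius for the asymptotic ratio
        for ph in phis:
            up = preset.uptake(float(ph))
            R_use = max(R_ref, 2 * critical_radius(ph, up, preset.geometry, preset.particle))
            ratios.append(
                aureole_width(R_use, ph, up, preset.geometry, preset.particle) / R_use
            )
        ax.plot(phis, ratios, label=f"{cfg.preset} conservation model")
    meas_path = out / "measurements.csv"
    if meas_path.exists():
        meas = pd.read_csv(meas_path)
        final = meas.iloc[-1]
        if final["R_um"] > 0:
            ax.plot(
                final["phi_S"],
                final["Delta_um"] / final["R_um"],
                "o",
                label="measured (final frame)",
            )
    ax.set_xlabel(r"substrate coverage $\varphi_S$")
    ax.set_ylabel(r"$\Delta/R$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "delta_over_R.png", dpi=120)
    plt.close(fig)
    paths.append(out / "delta_over_R.png")
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "render": _stage_render,
    "measure": _stage_measure,
    "fit": _stage_fit,
    "report": _stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the manifest.

    Returns the manifest: seed, config hash, and per-stage artifact hashes.
    Raises on any stage error (missing upstream artifacts raise
    DependencyError).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())
    manifest = {
        "seed": cfg.seed,
        "config_sha256": cfg.config_hash(),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        start = time.perf_counter()
        paths = _STAGE_FUNCS[stage](cfg, out)
        elapsed = time.perf_counter() - start
        logger.info("stage %-8s %d artifacts in %.2f s", stage, len(paths), elapsed)
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
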