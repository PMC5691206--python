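"""Synthetic data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here without any
experimental input:

* noisy spread-area time series following the linear wetting law,
* a discrete front-row uptake simulator in which the aureole *emerges* from
  integer particle bookkeeping rather than being imposed,
* a bright-field-like renderer (aggregate disk, cleared film, dark aureole
  annulus, speckled particle carpet),
* a confocal-like Z-stack renderer (cell body, nucleus, internalized beads).

All generators are seeded and byte-deterministic; rendered frames carry their
ground truth so measurement code can be validated by round-trip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

from .model import (
    CellGeometry,
    EnhancementParams,
    ParticleSpec,
    UptakeParams,
    enhanced_velocity,
    membrane_fraction,
)
from .presets import Preset, load_preset_params

__all__ = [
    "SimConfig",
    "SpreadingRecord",
    "FrontState",
    "FrontHistory",
    "OpticsConfig",
    "ImageFrame",
    "ZStack",
    "PackingError",
    "make_trajectory",
    "make_ensemble",
    "make_velocity_ladder",
    "simulate_front_uptake",
    "partition_row_load",
    "render_micrograph",
    "render_zstack",
    "write_frame",
    "read_frame",
    "write_zstack",
    "read_zstack",
]


class PackingError(RuntimeError):
    """Requested bead load cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """One synthetic spreading experiment.

    Defaults mirror the experimental protocol: aggregates of initial radius
    ~75 um imaged for 15 h at one frame every 10 min; trajectory noise is 5%
    multiplicative on the measured area with a per-aggregate velocity spread
    equal to the across-aggregate SD reported for the bare substrate.
    """

    preset: str = "bare"
    phi_S: float = 0.0
    R0_um: float = 75.0
    V_star_um_s: float | None = None  # None: from the preset enhancement law
    duration_s: float = 54000.0       # 15 h
    dt_s: float = 600.0               # 1 frame / 10 min
    area_noise: float = 0.05
    velocity_sd: float | None = None  # None: preset across-aggregate SD
    seed: int = 0
    geometry: CellGeometry = None
    particle: ParticleSpec = None
    uptake: UptakeParams = None
    enhancement: EnhancementParams = None

    def __post_init__(self) -> None:
        if self.area_noise < 0:
            raise ValueError("area_noise must be >= 0")
        if self.velocity_sd is not None and self.velocity_sd < 0:
            raise ValueError("velocity_sd must be >= 0")
        if self.phi_S < 0:
            raise ValueError("phi_S must be >= 0")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("duration and sampling interval must be > 0")
        p: Preset = load_preset_params(self.preset)
        if self.geometry is None:
            self.geometry = p.geometry
        if self.particle is None:
            self.particle = p.particle
        if self.uptake is None and p.phi_is > 0:
            self.uptake = p.uptake(self.phi_S)
        if self.enhancement is None:
            self.enhancement = p.enhancement
        if self.velocity_sd is None:
            self.velocity_sd = p.velocity_sd

    @property
    def V_star_eff(self) -> float:
        """Mean spreading velocity at this coverage [um/s]."""
        if self.V_star_um_s is not None:
            return self.V_star_um_s
        return enhanced_velocity(self.phi_S, self.enhancement)

    @property
    def times_s(self) -> np.ndarray:
        n = int(round(self.duration_s / self.dt_s))
        return np.arange(n + 1) * self.dt_s


@dataclass
class SpreadingRecord:
    """Per-aggregate spread-area time series (t, A) with its ground truth."""

    t_s: np.ndarray
    A_um2: np.ndarray
    R0_um: float
    A0_um2: float
    V_star_true: float
    label: str = ""

    @property
    def R_um(self) -> np.ndarray:
        return np.sqrt(self.A_um2 / math.pi)


# ---------------------------------------------------------------------------
# Spreading trajectories
# ---------------------------------------------------------------------------

def make_trajectory(cfg: SimConfig, rng: np.random.Generator | None = None) -> SpreadingRecord:
    """Simulate one aggregate: A(t) = A0 + R0 V_eff t with measurement noise.

    The aggregate's own velocity ``V_eff`` is drawn once from
    N(V*, velocity_sd) — aggregates genuinely differ — then each area sample
    gets independent multiplicative Gaussian noise of relative SD
    ``area_noise``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    t = cfg.times_s
    A0 = math.pi * cfg.R0_um**2
    V_eff = float(rng.normal(cfg.V_star_eff, cfg.velocity_sd))
    A = A0 + cfg.R0_um * V_eff * t
    if cfg.area_noise > 0:
        A = A * (1.0 + cfg.area_noise * rng.standard_normal(t.shape))
    A = np.maximum(A, 1.0)
    return SpreadingRecord(
        t_s=t, A_um2=A, R0_um=cfg.R0_um, A0_um2=A0, V_star_true=V_eff,
        label=f"{cfg.preset}:phi_S={cfg.phi_S}",
    )


def make_ensemble(cfg: SimConfig, n_aggregates: int) -> list[SpreadingRecord]:
    """n independent aggregates sharing one seeded random stream."""
    rng = np.random.default_rng(cfg.seed)
    return [make_trajectory(cfg, rng) for _ in range(n_aggregates)]


#: aggregates measured per coverage level of the silica ladder (study sizes)
LADDER_N_PER_LEVEL = (48, 9, 11, 11, 8, 10)
LADDER_LEVELS = (0.0, 0.04, 0.22, 0.44, 0.6, 0.71)


def make_velocity_ladder(
    enhancement: EnhancementParams,
    levels=LADDER_LEVELS,
    n_per_level=LADDER_N_PER_LEVEL,
    sd_frac: float = 0.15,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    with_se: bool = False,
) -> list[tuple]:
    """Per-coverage ensemble-mean velocities, as a V*(phi_S) experiment yields.

    At each coverage level, ``n`` aggregates are drawn with relative
    velocity SD ``sd_frac`` (the across-aggregate scatter of the printed
    error bars) and averaged — the fitted points of a real ladder are means
    over the aggregates measured at that coverage, so their sampling error
    shrinks as 1/sqrt(n).  Default sample sizes are the per-level counts of
    the silica series.  ``with_se=True`` appends each level's standard error
    of the mean (sample SD / sqrt(n)), usable as 1/SE fit weights.
    """
    if sd_frac < 0:
        raise ValueError("sd_frac must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = []
    for phi_S, n in zip(levels, n_per_level):
        mean_v = enhanced_velocity(phi_S, enhancement)
        draws = mean_v * (1.0 + sd_frac * rng.standard_normal(int(n)))
        if with_se:
            se = float(np.std(draws, ddof=1) / math.sqrt(n)) if n > 1 else float("inf")
            out.append((float(phi_S), float(np.mean(draws)), se))
        else:
            out.append((float(phi_S), float(np.mean(draws))))
    return out


# ---------------------------------------------------------------------------
# Discrete front-row uptake simulator
# ---------------------------------------------------------------------------

@dataclass
class FrontState:
    """Snapshot of the advancing front and its particle ledger.

    Rows are material cell cohorts riding at the film edge: row 0 is the
    leading row (annulus [R - d_cell, R]), row j sits j cell diameters
    behind.  ``internalized``/``adsorbed`` are integer particle counts per
    row; ``substrate_remaining`` counts particles still on the substrate
    ahead of the front; ``unclaimed`` counts swept particles no row could
    hold (only possible at extreme coverages).
    """

    t_s: float
    R_um: float
    delta_um: float
    internalized: tuple[int, ...]
    adsorbed: tuple[int, ...]
    substrate_remaining: int
    unclaimed: int
    phi_S: float
    R0_um: float

    @property
    def total_in_cells(self) -> int:
        return sum(self.internalized) + sum(self.adsorbed)


@dataclass
class FrontHistory:
    """Time series of FrontState snapshots plus the conserved total."""

    states: list[FrontState]
    n_total: int
    cfg: SimConfig = None

    @property
    def t_s(self) -> np.ndarray:
        return np.array([s.t_s for s in self.states])

    @property
    def R_um(self) -> np.ndarray:
        return np.array([s.R_um for s in self.states])

    @property
    def delta_um(self) -> np.ndarray:
        return np.array([s.delta_um for s in self.states])

    def conservation_ok(self) -> bool:
        """Exact integer balance at every snapshot."""
        return all(
            s.total_in_cells + s.unclaimed + s.substrate_remaining == self.n_total
            for s in self.states
        )

    @property
    def final(self) -> FrontState:
        return self.states[-1]


def _row_capacities(
    R: float, j: int, d_cell: float, A_cell: float, n_i_per_cell: float, n_s_per_cell: float
) -> tuple[int, int]:
    """Integer (internal, adsorbed) capacity of cohort row j at front radius R."""
    outer = R - j * d_cell
    inner = max(R - (j + 1) * d_cell, 0.0)
    if outer <= 0:
        return 0, 0
    cells = math.pi * (outer**2 - inner**2) / A_cell
    return round(cells * n_i_per_cell), round(cells * n_s_per_cell)


def simulate_front_uptake(cfg: SimConfig) -> FrontHistory:
    """Advance the film and let cell rows sweep up substrate particles.

    The front advances by the (noise-free) wetting law.  At each step the
    particles newly run over — the integer increment of
    round(nu pi (R^2 - R0^2)) — are offered to row 0 first; a row takes
    particles up to its internal capacity (phi_is V_cell / v_p per cell),
    then, above the threshold coverage, adsorbs up to its membrane capacity;
    leftovers pass inward to the next row.  The ledger
    in-cells + unclaimed + on-substrate is exact at every step, and the
    aureole width Delta = d_cell x (number of particle-loaded rows) emerges
    from the bookkeeping.
    """
    g, p, up = cfg.geometry, cfg.particle, cfg.uptake
    if cfg.phi_S > 0 and (p is None or up is None):
        raise ValueError("phi_S > 0 requires a particle and uptake parameters")
    if g.A_cell_um2 <= 0:  # pragma: no cover - CellGeometry already enforces
        raise ValueError("A_cell must be > 0")
    d_cell, A_cell = g.d_cell_um, g.A_cell_um2

    t = cfg.times_s
    A0 = math.pi * cfg.R0_um**2
    R_t = np.sqrt((A0 + cfg.R0_um * cfg.V_star_eff * t) / math.pi)

    if cfg.phi_S == 0 or p is None:
        nu = 0.0
        n_i_per_cell = n_s_per_cell = 0.0
    else:
        nu = 4.0 * cfg.phi_S / (math.pi * p.d_um**2)
        n_i_per_cell = up.phi_is * g.V_cell_um3 / p.volume_um3
        phi_s_now = membrane_fraction(cfg.phi_S, up)
        n_s_per_cell = 2.0 * phi_s_now * A_cell / (math.pi * p.d_um**2 / 4.0)

    n_total = round(nu * math.pi * (R_t[-1] ** 2 - cfg.R0_um**2))
    max_rows = int(R_t[-1] // d_cell) + 2

    load_i = [0] * max_rows
    load_s = [0] * max_rows
    unclaimed = 0
    swept_prev = 0
    states: list[FrontState] = []

    for tk, R in zip(t, R_t):
        swept_now = round(nu * math.pi * (R**2 - cfg.R0_um**2))
        new = swept_now - swept_prev
        swept_prev = swept_now
        j = 0
        while new > 0 and j < max_rows:
            cap_i, cap_s = _row_capacities(R, j, d_cell, A_cell, n_i_per_cell, n_s_per_cell)
            take = min(new, max(cap_i - load_i[j], 0))
            load_i[j] += take
            new -= take
            if new > 0:
                take = min(new, max(cap_s - load_s[j], 0))
                load_s[j] += take
                new -= take
            j += 1
        unclaimed += new

        n_loaded = sum(1 for a, b in zip(load_i, load_s) if a + b > 0)
        states.append(
            FrontState(
                t_s=float(tk),
                R_um=float(R),
                delta_um=d_cell * n_loaded,
                internalized=tuple(load_i[:n_loaded]),
                adsorbed=tuple(load_s[:n_loaded]),
                substrate_remaining=n_total - swept_now,
                unclaimed=unclaimed,
                phi_S=cfg.phi_S,
                R0_um=cfg.R0_um,
            )
        )

    return FrontHistory(states=states, n_total=n_total, cfg=cfg)


def partition_row_load(
    load: int, n_cells: int, mode: str = "uniform", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Split a row's integer particle load among its cells.

    ``uniform`` spreads the load as evenly as integers allow (the particle
    density inside the aureole is observed to be constant); ``multinomial``
    draws a random allocation for stochastic-heterogeneity studies.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if mode == "uniform":
        base, extra = divmod(load, n_cells)
        out = np.full(n_cells, base, dtype=int)
        out[:extra] += 1
        return out
    if mode == "multinomial":
        rng = np.random.default_rng() if rng is None else rng
        return rng.multinomial(load, np.full(n_cells, 1.0 / n_cells))
    raise ValueError(f"unknown partition mode {mode!r}")


# ---------------------------------------------------------------------------
# Bright-field-like rendering
# ---------------------------------------------------------------------------

@dataclass
class OpticsConfig:
    """Rendering geometry and grayscale levels (uint8)."""

    pixel_size_um: float = 2.0
    fov_um: float | None = None  # None: sized to fit the state
    level_aureole: int = 20
    level_aggregate: int = 45
    level_particle: int = 90
    level_background: int = 170
    level_film: int = 230

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")


@dataclass
class ImageFrame:
    """A 2D grayscale frame with calibration and embedded ground truth."""

    data: np.ndarray
    pixel_size_um: float
    ground_truth: dict = field(default_factory=dict)
    label: str = ""


def render_micrograph(
    state: FrontState,
    optics: OpticsConfig | None = None,
    seed: int = 0,
    d_cell_um: float = 22.0,
) -> ImageFrame:
    """Render a bright-field-like frame of a spreading aggregate.

    Concentric regions, inside out: aggregate disk (dark), cleared film
    (bright — visibly brighter than the coated substrate), aureole annulus
    of width Delta (darkest), then the particle carpet as Bernoulli speckle
    at surface fraction phi_S on a mid-gray background.  Pixel size must
    resolve a cell (>= 4 px per cell diameter) and the field of view must
    contain the aureole.
    """
    optics = optics or OpticsConfig()
    px = optics.pixel_size_um
    if d_cell_um / px < 4:
        raise ValueError(f"pixel size {px} um does not resolve cells (need >= 4 px/cell)")
    R, delta, R0 = state.R_um, state.delta_um, state.R0_um
    fov = optics.fov_um if optics.fov_um is not None else 2.3 * (R + delta)
    if fov < 2.0 * (R + delta):
        raise ValueError(
            f"field of view {fov} um smaller than the aureole extent {2 * (R + delta)} um"
        )
    n = int(round(fov / px))
    # pixel-center coordinates, origin at image center
    coords = (np.arange(n) - (n - 1) / 2.0) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(yy, xx)

    rng = np.random.default_rng(seed)
    img = np.full((n, n), optics.level_background, dtype=np.uint8)
    if state.phi_S > 0:
        speckle = rng.random((n, n)) < min(state.phi_S, 0.95)
        img[speckle] = optics.level_particle
    img[r <= R] = optics.level_film
    if delta > 0:
        img[(r <= R) & (r > R - delta)] = optics.level_aureole
    img[r <= R0] = optics.level_aggregate

    truth = {
        "t_s": state.t_s,
        "R_um": R,
        "delta_um": delta,
        "A_um2": math.pi * R**2,
        "phi_S": state.phi_S,
        "R0_um": R0,
    }
    return ImageFrame(data=img, pixel_size_um=px, ground_truth=truth, label="brightfield")


# ---------------------------------------------------------------------------
# Confocal-like Z-stacks
# ---------------------------------------------------------------------------

@dataclass
class ZStack:
    """Voxelized three-channel stack (cell body, nucleus, beads)."""

    channels: dict  # name -> (nz, ny, nx) uint8 array
    pixel_size_um: float
    z_step_um: float
    ground_truth: dict = field(default_factory=dict)


def render_zstack(
    g: CellGeometry,
    up: UptakeParams,
    p: ParticleSpec,
    seed: int = 0,
    bead_fraction: float | None = None,
    nucleus_fraction: float | None = None,
    pixel_size_um: float = 0.25,
    z_step_um: float = 0.25,
    noise_sd: float = 6.0,
    max_attempts_per_bead: int = 200,
) -> ZStack:
    """Voxelize a suspended cell containing a nucleus and internalized beads.

    The cell is a sphere of volume V_cell; the nucleus a concentric sphere
    at the requested volume fraction; beads are non-overlapping spheres of
    diameter d placed uniformly in the cytoplasm (outside the nucleus) by
    random sequential addition.  Slices are z_step apart (0.25 um, the
    confocal sampling).  True voxel-counted volumes are recorded.
    """
    bead_fraction = up.phi_is if bead_fraction is None else bead_fraction
    nucleus_fraction = g.nucleus_fraction if nucleus_fraction is None else nucleus_fraction
    if bead_fraction > 0.4:
        raise PackingError(
            f"bead volume fraction {bead_fraction} exceeds the 0.4 packing limit"
        )
    if not 0 <= nucleus_fraction < 1:
        raise ValueError("nucleus fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    r_cell = (3.0 * g.V_cell_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_nuc = r_cell * nucleus_fraction ** (1.0 / 3.0)
    r_bead = p.d_um / 2.0

    n_beads = round(bead_fraction * g.V_cell_um3 / p.volume_um3)
    centers: list[np.ndarray] = []
    if n_beads > 0:
        lo, hi = r_nuc + r_bead, r_cell - r_bead
        if hi <= lo:
            raise PackingError("no cytoplasmic shell available for beads")
        attempts_left = max_attempts_per_bead * n_beads
        while len(centers) < n_beads:
            if attempts_left <= 0:
                raise PackingError(
                    f"placed only {len(centers)}/{n_beads} beads within the retry budget"
                )
            attempts_left -= 1
            c = rng.uniform(-r_cell, r_cell, size=3)
            rad = np.linalg.norm(c)
            if not (lo <= rad <= hi):
                continue
            if any(np.linalg.norm(c - o) < p.d_um for o in centers):
                continue
            centers.append(c)

    # voxel grid: pixel centers, origin at the cell center
    half = r_cell + 4 * pixel_size_um
    nx = int(math.ceil(2 * half / pixel_size_um))
    nz = int(math.ceil(2 * half / z_step_um))
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_um
    zs = (np.arange(nz) - (nz - 1) / 2.0) * z_step_um
    Z, Y, X = np.meshgrid(zs, xs, xs, indexing="ij")

    r2 = X**2 + Y**2 + Z**2
    cell_mask = r2 <= r_cell**2
    nuc_mask = r2 <= r_nuc**2
    bead_mask = np.zeros_like(cell_mask)
    r_bead_px = r_bead / pixel_size_um
    r_bead_pz = r_bead / z_step_um
    for c in centers:
        iz = int(round(c[2] / z_step_um + (nz - 1) / 2.0))
        iy = int(round(c[1] / pixel_size_um + (nx - 1) / 2.0))
        ix = int(round(c[0] / pixel_size_um + (nx - 1) / 2.0))
        mz = int(math.ceil(r_bead_pz)) + 1
        mxy = int(math.ceil(r_bead_px)) + 1
        sl = (
            slice(max(iz - mz, 0), iz + mz + 1),
            slice(max(iy - mxy, 0), iy + mxy + 1),
            slice(max(ix - mxy, 0), ix + mxy + 1),
        )
        d2 = (X[sl] - c[0]) ** 2 + (Y[sl] - c[1]) ** 2 + (Z[sl] - c[2]) ** 2
        bead_mask[sl] |= d2 <= r_bead**2

    voxel = pixel_size_um**2 * z_step_um

    def _channel(mask: np.ndarray) -> np.ndarray:
        img = np.where(mask, 200.0, 0.0)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, mask.shape)
        return np.clip(img, 0, 255).astype(np.uint8)

    truth = {
        "V_cell_um3": float(cell_mask.sum() * voxel),
        "V_nucleus_um3": float(nuc_mask.sum() * voxel),
        "V_beads_um3": float(bead_mask.sum() * voxel),
        "bead_fraction_requested": float(bead_fraction),
        "nucleus_fraction_requested": float(nucleus_fraction),
        "n_beads": int(len(centers)),
    }
    return ZStack(
        channels={
            "cell": _channel(cell_mask),
            "nucleus": _channel(nuc_mask),
            "beads": _channel(bead_mask),
        },
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# TIFF I/O (frame/stack + YAML ground-truth sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path) -> str:
    return str(path) + ".truth.yaml"


def write_frame(frame: ImageFrame, path) -> None:
    """Write a frame as TIFF (calibration in the description) + truth sidecar."""
    desc = json.dumps({"pixel_size_um": frame.pixel_size_um, "label": frame.label})
    tifffile.imwrite(str(path), frame.data, description=desc)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(frame.ground_truth, fh)


def read_frame(path) -> ImageFrame:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = json.loads(tf.pages[0].description)
    truth = {}
    try:
        with open(_sidecar(path)) as fh:
            truth = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        pass
    return ImageFrame(
        data=data,
        pixel_size_um=desc["pixel_size_um"],
        ground_truth=truth,
        label=desc.get("label", ""),
    )


def write_zstack(stack: ZStack, path) -> None:
    """Write channels as a multi-page TIFF (axes ZCYX) + truth sidecar."""
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=1)
    desc = json.dumps(
        {
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "channels": names,
        }
    )
    tifffile.imwrite(
        str(path), data, description=desc, photometric="minisblack", planarconfig="separate"
    )
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(stack.ground_truth, fh)


def read_zstack(path) -> ZStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = json.loads(tf.pages[0].description)
    truth = {}
    try:
        with open(_sidecar(path)) as fh:
            truth = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        pass
    channels = {n: data[:, i] for i, n in enumerate(desc["channels"])}
    return ZStack(
        channels=channels,
        pixel_size_um=desc["pixel_size_um"],
        z_step_um=desc["z_step_um"],
        ground_truth=truth,
    )
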