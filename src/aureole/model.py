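"""Closed-form physics of cell-aggregate spreading on microparticle carpets.

A 3D cell aggregate deposited on an adhesive substrate spreads by emitting a
cellular monolayer (the *precursor film*), in close analogy with the wetting
of stratified droplets.  When the substrate is littered with sedimented
microparticles (MPs), the leading cells of the film phagocytose them, clearing
the substrate and forming a dark annulus of particle-laden cells — the
*aureole* — at the film periphery.

This module collects the algebra of that picture:

* sedimentation and coating of the substrate (sedimentation length,
  areal density ``nu = C*H``, surface fraction ``phi_S``),
* the diffusive spreading law ``(A - A0)/R0 = V* t`` and the friction-regime
  balance between permeation and slippage dissipation,
* the roughness enhancement of the spreading velocity
  ``V*(phi_S) = V*(0) (1 + alpha phi_S)`` clamped at a plateau,
* particle conservation in the aureole, which converts the aureole geometry
  (radius ``R``, width ``Delta``) into per-cell internalized and adsorbed
  particle loads.

Units are micrometres and seconds throughout, matching the scale of the
measurements; mass densities are in kg/m^3, thermal energy in joules, and the
conversion happens inside :func:`sedimentation_length` only.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

__all__ = [
    "ModelViolationError",
    "PhysicalConstants",
    "ParticleSpec",
    "CoatingSpec",
    "CellGeometry",
    "FrictionParams",
    "SpreadingParams",
    "EnhancementParams",
    "UptakeParams",
    "ClearingTimes",
    "sedimentation_length",
    "coating_from_suspension",
    "spread_area",
    "film_radius",
    "dissipation_terms",
    "permeation_dominant",
    "enhanced_velocity",
    "critical_radius",
    "aureole_width",
    "membrane_fraction",
    "conservation_residual",
    "particle_counts",
    "passage_time",
    "clearing_feasible",
]


class ModelViolationError(ValueError):
    """Raised when inputs contradict the particle-conservation model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


class _ConfigMixin:
    """YAML-friendly dict round-trip; keys mirror the field names."""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict):
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PhysicalConstants(_ConfigMixin):
    """Thermal energy k_B*T [J], gravity g [m/s^2], medium density [kg/m^3]."""

    kBT_J: float = 4.11e-21  # k_B * 298 K
    g_m_s2: float = 9.81
    rho_medium_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        _check_positive(self, "kBT_J", "g_m_s2", "rho_medium_kg_m3")


@dataclass
class ParticleSpec(_ConfigMixin):
    """A microparticle type: diameter [um], mass density [kg/m^3].

    ``cluster_factor`` is the effective number of primary particles per
    internalized unit, >= 1; flocculating particles (amine-functionalized
    polystyrene in culture medium) are taken up as clusters, so reported
    per-cell counts are counts of clusters.
    """

    d_um: float
    rho_kg_m3: float
    cluster_factor: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        _check_positive(self, "d_um", "rho_kg_m3")
        if self.cluster_factor < 1:
            raise ValueError("cluster_factor must be >= 1")

    @property
    def volume_um3(self) -> float:
        """Particle volume v_p = (pi/6) d^3 [um^3]."""
        return math.pi / 6.0 * self.d_um**3


@dataclass
class CoatingSpec(_ConfigMixin):
    """Substrate coating: areal density nu [um^-2] and surface fraction phi_S.

    ``phi_S`` may exceed 1 when heavy particles pile into several layers.
    """

    nu_um2: float
    phi_S: float
    C_um3: float | None = None  # suspension concentration, if known
    H_um: float | None = None   # chamber height, if known

    def __post_init__(self) -> None:
        if self.nu_um2 < 0:
            raise ValueError("areal density nu must be >= 0")
        if self.phi_S < 0:
            raise ValueError("surface fraction phi_S must be >= 0")


@dataclass
class CellGeometry(_ConfigMixin):
    """Cell dimensions: first-row diameter, volume, projected area [um units].

    ``d_cell`` and ``V_cell`` are independent measurements (spread first-row
    cells are not spheres), so ``(pi/6) d_cell^3 != V_cell`` in general.
    ``V_cell`` defaults to 1600 um^3 — the value used in the conservation
    algebra; the suspended-cell measurement gives 1620 um^3 and can be set
    explicitly.
    """

    d_cell_um: float = 22.0
    V_cell_um3: float = 1600.0
    A_cell_um2: float = 770.0
    nucleus_fraction: float = 0.25

    def __post_init__(self) -> None:
        _check_positive(self, "d_cell_um", "V_cell_um3", "A_cell_um2")
        if not 0 <= self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must be in [0, 1)")


@dataclass
class FrictionParams(_ConfigMixin):
    """Dissipation parameters of the spreading film.

    eta: tissue viscosity; k: film-substrate friction coefficient;
    xi: width of the permeation region; S: spreading parameter (driving
    force per unit contact-line length); contact_radius R_L: radius of the
    aggregate/film contact line (~ aggregate radius R0).  Any consistent
    unit system; only ratios enter the regime check.
    """

    eta: float
    k: float
    xi: float
    S: float = 0.0
    contact_radius: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(self, "eta", "xi", "contact_radius")
        if self.k < 0:
            raise ValueError("friction coefficient k must be >= 0")


@dataclass
class SpreadingParams(_ConfigMixin):
    """Linear spreading law parameters: A(t) = A0 + R0 V* t."""

    V_star_um_s: float
    R0_um: float
    A0_um2: float | None = None

    def __post_init__(self) -> None:
        _check_positive(self, "R0_um")
        if self.A0_um2 is None:
            # aggregate treated as spherical: initial film area pi R0^2
            self.A0_um2 = math.pi * self.R0_um**2

    @property
    def D_um2_s(self) -> float:
        """Diffusion coefficient of the spreading law, D = V* R0."""
        return self.V_star_um_s * self.R0_um


@dataclass
class EnhancementParams(_ConfigMixin):
    """Roughness enhancement of the spreading velocity.

    V0: bare-substrate velocity [um/s]; alpha: excess-area coefficient;
    phi_S_plateau: coverage at which V* stops increasing (dense sphere
    packing, ~0.6).
    """

    V0_um_s: float
    alpha: float
    phi_S_plateau: float = 0.6

    def __post_init__(self) -> None:
        _check_positive(self, "V0_um_s", "phi_S_plateau")
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


@dataclass
class UptakeParams(_ConfigMixin):
    """Saturation uptake parameters of the leading cells.

    phi_is: maximum volume fraction of a cell occupied by internalized MPs;
    phi_s: surface fraction of the cell membrane covered by adsorbed MPs;
    a, phi_S0: parameters of the adsorption law phi_s = a (phi_S - phi_S0)
    above the threshold coverage phi_S0.
    """

    phi_is: float
    phi_s: float = 0.0
    a: float = 0.9
    phi_S0: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.phi_is < 1:
            raise ValueError("phi_is must be in [0, 1)")
        if self.phi_s < 0:
            raise ValueError("phi_s must be >= 0")
        if self.a < 0:
            raise ValueError("slope a must be >= 0")


@dataclass
class ClearingTimes(_ConfigMixin):
    """Internalization time tau_i and front passage time tau_p [s]."""

    tau_i_s: float
    tau_p_s: float

    def __post_init__(self) -> None:
        if self.tau_i_s < 0 or self.tau_p_s < 0:
            raise ValueError("times must be >= 0")


# ---------------------------------------------------------------------------
# Sedimentation and coating
# ---------------------------------------------------------------------------

def sedimentation_length(
    p: ParticleSpec, const: PhysicalConstants | None = None
) -> tuple[float, bool]:
    """Gravitational sedimentation length l_S = k_B T / (v_p dRho g) [um].

    Returns ``(l_S_um, sediments)``.  ``sediments`` is False (and l_S is
    +inf) for neutrally buoyant or buoyant particles, which never settle;
    l_S smaller than the particle diameter means all particles fall to the
    chamber bottom.
    """
    const = const or PhysicalConstants()
    delta_rho = p.rho_kg_m3 - const.rho_medium_kg_m3
    if delta_rho <= 0:
        return math.inf, False
    v_p_m3 = p.volume_um3 * 1e-18
    l_s_m = const.kBT_J / (v_p_m3 * delta_rho * const.g_m_s2)
    return l_s_m * 1e6, True


def coating_from_suspension(
    C_um3: float,
    H_um: float,
    p: ParticleSpec,
    fully_sedimented: bool = True,
    measured_nu_um2: float | None = None,
) -> CoatingSpec:
    """Coating produced by letting a suspension settle in the chamber.

    When all particles sediment (l_S < d), the areal density is nu = C * H
    with H the chamber height.  Otherwise nu cannot be predicted from the
    suspension and must be measured optically and passed in.
    """
    if C_um3 < 0:
        raise ValueError("concentration must be >= 0")
    if H_um <= 0:
        raise ValueError("chamber height must be > 0")
    if fully_sedimented:
        nu = C_um3 * H_um
    elif measured_nu_um2 is not None:
        nu = measured_nu_um2
    else:
        raise ValueError(
            "particles do not fully sediment (l_S > d): the areal density "
            "cannot be predicted from C*H and must be measured optically"
        )
    phi_S = nu * math.pi * p.d_um**2 / 4.0
    return CoatingSpec(nu_um2=nu, phi_S=phi_S, C_um3=C_um3, H_um=H_um)


# ---------------------------------------------------------------------------
# Spreading law and friction regime
# ---------------------------------------------------------------------------

def spread_area(t_s, sp: SpreadingParams):
    """Spread area A(t) = A0 + R0 V* t [um^2] of the precursor film.

    The spreading is diffusive: A grows linearly in time with slope
    R0 V* = D.  Accepts scalar or array times.
    """
    import numpy as np

    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    A = sp.A0_um2 + sp.R0_um * sp.V_star_um_s * t
    return float(A) if np.isscalar(t_s) else A


def film_radius(A_um2):
    """Equivalent-circle radius R = sqrt(A/pi) of a film of area A."""
    import numpy as np

    return np.sqrt(np.asarray(A_um2, dtype=float) / math.pi)[()]


def dissipation_terms(
    R: float, R_dot: float, fp: FrictionParams
) -> tuple[float, float]:
    """Permeation and slippage dissipation of the expanding film.

    permeation = 2 pi eta R Rdot^2 / R_L  (cells entering the film through
    the contact region); slippage = 2 pi k R^2 Rdot^2 ln(R/R_L) (film
    sliding on the substrate).  Requires R >= R_L.
    """
    R_L = fp.contact_radius
    if R < R_L:
        raise ValueError(f"film radius R={R} must be >= contact radius R_L={R_L}")
    permeation = 2.0 * math.pi * fp.eta * R * R_dot**2 / R_L
    slippage = 2.0 * math.pi * fp.k * R**2 * R_dot**2 * math.log(R / R_L)
    return permeation, slippage


def permeation_dominant(fp: FrictionParams, R: float, R_L: float | None = None) -> bool:
    """True when permeation dissipation dominates: eta/R_L > k ln(R/R_L).

    This is the regime of cell aggregates, whose bulk viscosity far exceeds
    the sliding friction; it justifies the linear A(t) law.
    """
    R_L = fp.contact_radius if R_L is None else R_L
    if R < R_L or R_L <= 0:
        raise ValueError("need R >= R_L > 0")
    return fp.eta / R_L > fp.k * math.log(R / R_L)


def enhanced_velocity(phi_S: float, ep: EnhancementParams) -> float:
    """Spreading velocity on a particle carpet, V*(phi_S) [um/s].

    Sedimented particles roughen the substrate and increase the
    cell-substrate interface, hence the spreading parameter:
    V* = V0 (1 + alpha phi_S), saturating at phi_S_plateau (hard clamp —
    the velocity remains constant above dense packing).
    """
    if phi_S < 0:
        raise ValueError("phi_S must be >= 0")
    return ep.V0_um_s * (1.0 + ep.alpha * min(phi_S, ep.phi_S_plateau))


# ---------------------------------------------------------------------------
# Aureole particle conservation
# ---------------------------------------------------------------------------

def critical_radius(
    phi_S: float, up: UptakeParams, g: CellGeometry, p: ParticleSpec
) -> float:
    """Film radius R_c at which the leading cell row saturates with MPs [um].

    R_c phi_S = 3 phi_is (d_cell/d) (V_cell/A_cell): the particles swept from
    a disk of radius R_c exactly fill the first row of cells to volume
    fraction phi_is.  phi_S = 0 gives +inf (the leading row never saturates).
    """
    if phi_S < 0:
        raise ValueError("phi_S must be >= 0")
    if up.phi_is <= 0:
        raise ValueError("phi_is must be > 0 for a saturation radius")
    coefficient = 3.0 * up.phi_is * (g.d_cell_um / p.d_um) * (g.V_cell_um3 / g.A_cell_um2)
    if phi_S == 0:
        return math.inf
    return coefficient / phi_S


def aureole_width(
    R_um: float, phi_S: float, up: UptakeParams, g: CellGeometry, p: ParticleSpec
) -> float:
    """Aureole width Delta(R) [um] from particle conservation.

    Below the saturation radius R_c the aureole is the first cell row,
    Delta = d_cell.  Above R_c the swept particles are shared between
    internalization (volume fraction phi_is) and membrane adsorption
    (surface fraction phi_s), and

        Delta (3 phi_is V_cell / (d A_cell) + 4 phi_s) = R phi_S.

    The two branches are continuous at R = R_c when phi_s = 0.  Fractions
    are invariant under particle clustering, so no cluster correction
    enters here (it only rescales particle *counts*).
    """
    if R_um <= 0:
        raise ValueError("R must be > 0")
    if phi_S < 0:
        raise ValueError("phi_S must be >= 0")
    if phi_S == 0:
        return 0.0
    if up.phi_is == 0 and up.phi_s == 0:
        raise ModelViolationError(
            "phi_S > 0 with phi_is = phi_s = 0: swept particles have nowhere to go"
        )
    R_c = critical_radius(phi_S, up, g, p) if up.phi_is > 0 else 0.0
    if R_um <= R_c:
        return g.d_cell_um
    denom = 3.0 * up.phi_is * g.V_cell_um3 / (p.d_um * g.A_cell_um2) + 4.0 * up.phi_s
    return R_um * phi_S / denom


def membrane_fraction(phi_S: float, up: UptakeParams) -> float:
    """Adsorbed membrane fraction phi_s(phi_S) = max(0, a (phi_S - phi_S0)).

    Below the threshold coverage phi_S0 all swept particles are
    internalized; above it the excess adsorbs linearly on the membrane.
    """
    return max(0.0, up.a * (phi_S - up.phi_S0))


def conservation_residual(
    R_um: float,
    Delta_um: float,
    C_i_um3: float,
    C_S_um2: float,
    g: CellGeometry,
    nu_um2: float,
) -> float:
    """Residual of the aureole particle balance, normalized when possible.

    The number of MPs held by the aureole (annulus area 2 pi R Delta,
    cells of projected area A_cell each holding C_i V_cell internal plus
    2 C_S A_cell adsorbed particles — both membrane faces) must equal the
    number swept from the substrate, pi R^2 nu:

        (2 pi R Delta / A_cell)(C_i V_cell + 2 C_S A_cell) - pi R^2 nu.

    Returned divided by pi R^2 nu when nu > 0.
    """
    if min(R_um, Delta_um, C_i_um3, C_S_um2, nu_um2) < 0:
        raise ValueError("all inputs must be >= 0")
    held = (2.0 * math.pi * R_um * Delta_um / g.A_cell_um2) * (
        C_i_um3 * g.V_cell_um3 + 2.0 * C_S_um2 * g.A_cell_um2
    )
    swept = math.pi * R_um**2 * nu_um2
    residual = held - swept
    if swept > 0:
        return residual / swept
    return residual


def particle_counts(
    up: UptakeParams, g: CellGeometry, p: ParticleSpec
) -> tuple[int, int, int]:
    """Per-cell particle loads (n_i internalized, n_s adsorbed, n_tot).

    n_i = phi_is V_cell / v_p; n_s = 2 phi_s A_cell / (pi d^2 / 4) counts
    both membrane faces.  For flocculating particles the counts are numbers
    of clusters: both are divided by ``cluster_factor``.
    """
    n_i = up.phi_is * g.V_cell_um3 / p.volume_um3 / p.cluster_factor
    n_s = 2.0 * up.phi_s * g.A_cell_um2 / (math.pi * p.d_um**2 / 4.0) / p.cluster_factor
    n_i_int, n_s_int = round(n_i), round(n_s)
    return n_i_int, n_s_int, n_i_int + n_s_int


# ---------------------------------------------------------------------------
# Clearing feasibility
# ---------------------------------------------------------------------------

def passage_time(g: CellGeometry, V_star_um_s: float) -> float:
    """Time tau_p = d_cell / V* [s] a leading cell spends over fresh substrate.

    A stalled front (V* = 0) gives +inf: the leading cell sits on the same
    patch forever.
    """
    if V_star_um_s < 0:
        raise ValueError("V* must be >= 0")
    if V_star_um_s == 0:
        return math.inf
    return g.d_cell_um / V_star_um_s


def clearing_feasible(ct: ClearingTimes) -> bool:
    """True when the front can clear the substrate: tau_i < tau_p (strict).

    Internalization must complete before the cell has moved one cell
    diameter; ~5 um beads take longer than tau_p and are not internalized.
    """
    return ct.tau_i_s < ct.tau_p_s
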