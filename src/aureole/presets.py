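"""Parameter presets for the studied particle types.

Each preset bundles the measured constants for one substrate condition:
bare fibronectin-coated glass, or carpets of silica/polystyrene
microparticles.  Values are the published per-type estimates (saturation
volume fraction phi_is, adsorption threshold phi_S0, plateau spreading
velocities, enhancement coefficient alpha), together with the coverage
levels actually prepared, so synthetic experiments run under the same
conditions as the real ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CellGeometry, EnhancementParams, ParticleSpec, UptakeParams

__all__ = ["Preset", "PRESETS", "load_preset_params", "preset_names"]

#: Bare-substrate spreading velocity and its across-aggregate SD [um/s].
V_STAR_BARE = 4.9e-2
V_STAR_BARE_SD = 0.9e-2

#: Enhancement fit: V*(phi_S) = V0 (1 + alpha phi_S), plateau at phi_S = 0.6.
ALPHA = 1.3
PHI_S_PLATEAU = 0.6


@dataclass(frozen=True)
class Preset:
    """One experimental condition: particle type + fitted model parameters."""

    name: str
    particle: ParticleSpec | None
    geometry: CellGeometry
    enhancement: EnhancementParams
    phi_is: float
    phi_S0: float
    a: float
    #: coverage ladder prepared for this particle type
    phi_S_levels: tuple[float, ...] = ()
    #: measured membrane fractions phi_s at the coverages above threshold
    phi_s_by_level: dict = field(default_factory=dict)
    #: plateau spreading velocity reported for this type [um/s]
    V_star_plateau: float = V_STAR_BARE
    velocity_sd: float = V_STAR_BARE_SD

    def uptake(self, phi_S: float | None = None) -> UptakeParams:
        """Uptake parameters, with phi_s looked up (or derived) for phi_S."""
        if phi_S is None:
            phi_s = 0.0
        elif phi_S in self.phi_s_by_level:
            phi_s = self.phi_s_by_level[phi_S]
        else:
            phi_s = max(0.0, self.a * (phi_S - self.phi_S0))
        return UptakeParams(phi_is=self.phi_is, phi_s=phi_s, a=self.a, phi_S0=self.phi_S0)


_GEOMETRY = CellGeometry()  # d_cell 22 um, V_cell 1600 um^3, A_cell 770 um^2

PRESETS: dict[str, Preset] = {
    "bare": Preset(
        name="bare",
        particle=None,
        geometry=_GEOMETRY,
        enhancement=EnhancementParams(V0_um_s=V_STAR_BARE, alpha=0.0),
        phi_is=0.0,
        phi_S0=0.0,
        a=0.0,
        phi_S_levels=(0.0,),
        V_star_plateau=V_STAR_BARE,
    ),
    "SiO2Carbo1000": Preset(
        name="SiO2Carbo1000",
        particle=ParticleSpec(d_um=1.0, rho_kg_m3=2000.0, label="SiO2Carbo1000"),
        geometry=_GEOMETRY,
        enhancement=EnhancementParams(
            V0_um_s=V_STAR_BARE, alpha=ALPHA, phi_S_plateau=PHI_S_PLATEAU
        ),
        phi_is=0.21,
        phi_S0=0.46,
        a=0.9,
        phi_S_levels=(0.04, 0.22, 0.44, 0.71, 1.06, 1.42),
        phi_s_by_level={0.22: 0.0, 0.44: 0.0, 0.71: 0.22, 1.06: 0.57, 1.42: 0.87},
        V_star_plateau=9.6e-2,
        velocity_sd=1.1e-2,
    ),
    "PsCarbo1000": Preset(
        name="PsCarbo1000",
        particle=ParticleSpec(d_um=1.0, rho_kg_m3=1050.0, label="PsCarbo1000"),
        geometry=_GEOMETRY,
        enhancement=EnhancementParams(
            V0_um_s=V_STAR_BARE, alpha=ALPHA, phi_S_plateau=PHI_S_PLATEAU
        ),
        phi_is=0.11,
        phi_S0=0.2,
        a=0.9,
        phi_S_levels=(0.02, 0.13, 0.19, 0.23, 0.8, 1.2),
        phi_s_by_level={0.13: 0.0, 0.19: 0.0, 0.23: 0.0, 0.8: 0.43, 1.2: 0.80},
        V_star_plateau=8.8e-2,
        velocity_sd=1.7e-2,
    ),
    "PsAmine200": Preset(
        name="PsAmine200",
        # hydrodynamic diameter 0.8 um; suspensions flocculate in medium, so
        # per-cell counts are counts of clusters — cluster_factor is free.
        particle=ParticleSpec(
            d_um=0.8, rho_kg_m3=1050.0, cluster_factor=1.0, label="PsAmine200"
        ),
        geometry=_GEOMETRY,
        enhancement=EnhancementParams(V0_um_s=5.9e-2, alpha=0.0),
        phi_is=0.23,
        phi_S0=0.5,
        a=0.9,
        phi_S_levels=(0.05, 0.31, 0.40, 0.45, 0.8, 1.2),
        phi_s_by_level={0.8: 0.28, 1.2: 0.47},
        V_star_plateau=5.9e-2,
        velocity_sd=2.0e-2,
    ),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def load_preset_params(name: str) -> Preset:
    """Look up a preset by name; unknown names list the available ones."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(preset_names())}"
        ) from None
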