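"""Assembly of the labeled voxel volume for one scenario and pulse position.

The z-stack from the surface is: one voxel layer of epidermis (optically
rescaled to its 0.010 cm true thickness), the scenario's dermis, then
subcutaneous adipose tissue.  The radial artery (vessel wall + blood-filled
lumen, dilated by the travelling pulse envelope) is embedded at the
scenario's depth, which is measured from the surface to the *top* of the
baseline lumen; the lumen axis therefore sits at
``artery_depth + inner_diameter/2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .grid import GridSpec
from .optical_properties import (
    ChromophoreModel,
    MediumTable,
    MelaninSetting,
    ObesityScenario,
    dermis_adjusted_mu_a,
    epidermis_melanin_mu_a,
    scale_thin_layer,
)
from .pulse_geometry import PulseShape, lumen_mask, wall_mask
from .vessel_mechanics import VesselSpec

__all__ = [
    "MediaLabel",
    "VoxelGrid",
    "EPIDERMIS_TRUE_THICKNESS_CM",
    "build_volume",
    "lumen_axis_depth",
    "scenario_series",
    "isolated_factor_scenarios",
    "combined_obesity_scenarios",
    "ISOLATED_FACTORS",
]

#: True (anatomical) epidermis thickness represented by the top voxel layer.
EPIDERMIS_TRUE_THICKNESS_CM = 0.010


class MediaLabel(IntEnum):
    EPIDERMIS = 0
    DERMIS = 1
    SUBCUTIS = 2
    VESSEL_WALL = 3
    BLOOD = 4


@dataclass(frozen=True)
class VoxelGrid:
    """Labeled media map plus the per-label optical property table.

    ``properties[label] = (mu_a, mu_s, g, n)`` for each MediaLabel row.
    """

    grid: GridSpec
    media: np.ndarray  # uint8, shape (nx, ny, nz)
    properties: np.ndarray  # float64, shape (n_labels, 4)

    def __post_init__(self) -> None:
        if self.media.shape != (self.grid.nx, self.grid.ny, self.grid.nz):
            raise ValueError("media array does not match the grid dimensions")
        if self.media.max() >= self.properties.shape[0]:
            raise ValueError("a voxel label has no property row")

    def label_counts(self) -> dict[str, int]:
        counts = np.bincount(self.media.ravel(), minlength=len(MediaLabel))
        return {label.name.lower(): int(counts[label]) for label in MediaLabel}


def lumen_axis_depth(scenario: ObesityScenario, vessel: VesselSpec) -> float:
    """Depth of the lumen axis: scenario depth (to lumen top) + baseline radius."""
    return scenario.artery_depth_cm + vessel.inner_diameter_cm / 2.0


def build_volume(
    scenario: ObesityScenario,
    melanin: MelaninSetting,
    wavelength: int,
    shape: PulseShape,
    y_position: float,
    *,
    grid: GridSpec | None = None,
    vessel: VesselSpec | None = None,
    table: MediumTable | None = None,
    chromophores: ChromophoreModel | None = None,
) -> VoxelGrid:
    """Build the labeled volume for one pulse position.

    The pulse shape's axis depth ``shape.d`` must equal
    ``lumen_axis_depth(scenario, vessel)``; it is part of the shape so mask
    construction stays independent of scenarios.
    """
    grid = grid or GridSpec()
    vessel = vessel or VesselSpec()
    table = table or MediumTable()
    chromophores = chromophores or ChromophoreModel()

    dz = grid.dz
    dermis_bottom = dz + scenario.dermal_thickness_cm
    if dermis_bottom >= grid.lz_cm:
        raise ValueError("dermis extends beyond the grid depth")
    axis_d = shape.d
    max_radius = max(shape.IDx, shape.IDxd, vessel.inner_diameter_cm) / 2.0
    if axis_d + max_radius + vessel.wall_thickness_cm > grid.lz_cm:
        raise ValueError("artery (wall included) extends beyond the grid depth")
    if axis_d - max_radius - vessel.wall_thickness_cm < dz:
        raise ValueError("artery reaches the epidermis layer")
    # a thick dermis may extend past the artery top (the isolated
    # dermal-thickness series does); the vessel simply overrides it

    z = grid.z_centers()
    media = np.full((grid.nx, grid.ny, grid.nz), MediaLabel.SUBCUTIS, dtype=np.uint8)
    media[:, :, z < dz] = MediaLabel.EPIDERMIS  # exactly the top voxel layer
    media[:, :, (z >= dz) & (z < dermis_bottom)] = MediaLabel.DERMIS

    lumen = lumen_mask(grid, vessel, shape, y_position)
    wall = wall_mask(grid, vessel, lumen)
    media[wall] = MediaLabel.VESSEL_WALL
    media[lumen] = MediaLabel.BLOOD

    props = np.zeros((len(MediaLabel), 4))
    epi = table.get("epidermis", wavelength)
    epi_mu_a = epidermis_melanin_mu_a(wavelength, melanin, chromophores, table)
    epi_scaled = scale_thin_layer(
        type(epi)(epi_mu_a, epi.mu_s, epi.g, epi.n), EPIDERMIS_TRUE_THICKNESS_CM, dz
    )
    props[MediaLabel.EPIDERMIS] = (epi_scaled.mu_a, epi_scaled.mu_s, epi_scaled.g, epi_scaled.n)
    der = table.get("dermis", wavelength)
    props[MediaLabel.DERMIS] = (
        dermis_adjusted_mu_a(wavelength, scenario, chromophores, table),
        der.mu_s,
        der.g,
        der.n,
    )
    for label, medium in (
        (MediaLabel.SUBCUTIS, "subcutis"),
        (MediaLabel.VESSEL_WALL, "vessel_wall"),
        (MediaLabel.BLOOD, "blood"),
    ):
        p = table.get(medium, wavelength)
        props[label] = (p.mu_a, p.mu_s, p.g, p.n)

    return VoxelGrid(grid=grid, media=media, properties=props)


ISOLATED_FACTORS = ("tewl", "blood", "dermal_thickness", "artery_depth")


def isolated_factor_scenarios(
    factor: str, levels: tuple[ObesityScenario, ...] | None = None
) -> list[ObesityScenario]:
    """Scenario series varying exactly one factor, others at the BMI-25 row."""
    from .optical_properties import DEFAULT_SCENARIOS

    levels = levels or DEFAULT_SCENARIOS
    if not levels:
        raise ValueError("empty scenario list")
    base = levels[0]
    out = []
    for row in levels:
        if factor == "tewl":
            s = ObesityScenario(row.bmi, row.tewl_pct, base.blood_change_pct,
                                base.dermal_thickness_cm, base.artery_depth_cm)
        elif factor == "blood":
            s = ObesityScenario(row.bmi, base.tewl_pct, row.blood_change_pct,
                                base.dermal_thickness_cm, base.artery_depth_cm)
        elif factor == "dermal_thickness":
            s = ObesityScenario(row.bmi, base.tewl_pct, base.blood_change_pct,
                                row.dermal_thickness_cm, base.artery_depth_cm)
        elif factor == "artery_depth":
            s = ObesityScenario(row.bmi, base.tewl_pct, base.blood_change_pct,
                                base.dermal_thickness_cm, row.artery_depth_cm)
        else:
            raise ValueError(f"unknown factor {factor!r}; one of {ISOLATED_FACTORS}")
        out.append(s)
    return out


def combined_obesity_scenarios() -> list[ObesityScenario]:
    """Four combined obesity levels (non-obese, obese 1-3).

    Dermal thickness grows linearly 0.10 -> 0.25 cm and artery depth
    0.25 -> 0.45 cm; water/blood content stay at baseline (these series
    isolate the geometric changes of obesity).
    """
    thickness = np.linspace(0.10, 0.25, 4)
    depth = np.linspace(0.25, 0.45, 4)
    bmi = (25, 30, 35, 40)
    return [
        ObesityScenario(b, 0.0, 0.0, float(t), float(d))
        for b, t, d in zip(bmi, thickness, depth)
    ]


def scenario_series(levels: list[ObesityScenario], **kwargs):
    """One volume builder (closure over build_volume) per scenario level."""
    import functools

    if not levels:
        raise ValueError("empty scenario list")
    return [functools.partial(build_volume, scenario, **kwargs) for scenario in levels]
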