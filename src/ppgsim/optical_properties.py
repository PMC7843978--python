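"""Per-medium optical properties at the two source wavelengths, and the
physiological adjustments applied to them.

The simulator works with five media (epidermis, dermis, subcutis, vessel wall,
blood) characterized at the 660 nm and 890 nm peaks of the modeled pulse
oximeter.  Two kinds of adjustment are supported:

* **Obesity**: trans-epidermal water loss (TEWL) reduces the dermal water
  fraction and dermal perfusion raises the blood fraction; both enter the
  dermis absorption coefficient through a three-component chromophore mixture
  (blood + water + residual dry matrix).  The residual is calibrated so the
  non-obese scenario reproduces the default dermis value exactly, which makes
  the mixture independent of the particular water/blood absorption
  compilation used.
* **Melanin**: the epidermal absorption coefficient is a volume-fraction
  mixture of a melanosome reference spectrum and a non-melanin baseline,
  calibrated the same way at a reference fraction.

Scattering coefficients, anisotropy and refractive indices are deliberately
left untouched by both adjustments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "OpticalProperties",
    "MediumTable",
    "ObesityScenario",
    "MelaninSetting",
    "ChromophoreModel",
    "MEDIA",
    "WAVELENGTHS",
    "DEFAULT_SCENARIOS",
    "baseline_properties",
    "scale_thin_layer",
    "dermis_adjusted_mu_a",
    "epidermis_melanin_mu_a",
]

MEDIA = ("epidermis", "dermis", "subcutis", "vessel_wall", "blood")
WAVELENGTHS = (660, 890)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/scattering/anisotropy/refractive index of one medium.

    Units: ``mu_a`` and ``mu_s`` in cm^-1; ``g`` and ``n`` dimensionless.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must lie in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")


# Default media table.  The dermis absorption at 890 nm is 2.459 cm^-1: the
# value is stored on the same scale as the 660 nm column (a raw "2459" would
# be physically implausible for dermis).  All values overridable via config.
_DEFAULT_MEDIA: dict[tuple[str, int], OpticalProperties] = {
    ("epidermis", 660): OpticalProperties(0.3442, 121.2, 0.7, 1.47),
    ("epidermis", 890): OpticalProperties(0.3184, 224.7, 0.7, 1.47),
    ("dermis", 660): OpticalProperties(0.5453, 208.6, 0.7, 1.47),
    ("dermis", 890): OpticalProperties(2.459, 116.7, 0.7, 1.47),
    ("subcutis", 660): OpticalProperties(0.0001, 249.7, 0.7, 1.47),
    ("subcutis", 890): OpticalProperties(0.0217, 189.8, 0.7, 1.47),
    ("vessel_wall", 660): OpticalProperties(0.8, 230.0, 0.9, 1.4),
    ("vessel_wall", 890): OpticalProperties(0.8, 230.0, 0.9, 1.4),
    ("blood", 660): OpticalProperties(2.026, 75.76, 0.9, 1.4),
    ("blood", 890): OpticalProperties(6.32, 56.18, 0.9, 1.4),
}


class MediumTable:
    """Mapping ``(medium, wavelength nm) -> OpticalProperties``.

    Every supported (medium, wavelength) pair must be present.
    """

    def __init__(self, entries: Mapping[tuple[str, int], OpticalProperties] | None = None):
        table = dict(_DEFAULT_MEDIA)
        if entries:
            for key, props in entries.items():
                medium, wl = key
                if medium not in MEDIA or wl not in WAVELENGTHS:
                    raise KeyError(f"unsupported medium/wavelength: {key!r}")
                table[(medium, int(wl))] = props
        self._table = table

    def get(self, medium: str, wavelength: int) -> OpticalProperties:
        try:
            return self._table[(medium, int(wavelength))]
        except KeyError:
            raise KeyError(
                f"unsupported medium/wavelength pair ({medium!r}, {wavelength!r}); "
                f"supported media: {MEDIA}, wavelengths: {WAVELENGTHS}"
            ) from None

    def to_dict(self) -> dict:
        return {
            f"{medium}@{wl}": dataclasses.asdict(props)
            for (medium, wl), props in sorted(self._table.items())
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, float]]) -> "MediumTable":
        entries = {}
        for key, values in data.items():
            medium, wl = key.rsplit("@", 1)
            entries[(medium, int(wl))] = OpticalProperties(**values)
        return cls(entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MediumTable) and self._table == other._table


@dataclass(frozen=True)
class ObesityScenario:
    """One row of the BMI-coupled physiological parameter set.

    ``tewl_pct`` reduces dermal water; ``blood_change_pct`` increases dermal
    blood; ``dermal_thickness_cm`` and ``artery_depth_cm`` (surface to top of
    the lumen) change the geometry directly.
    """

    bmi: float
    tewl_pct: float
    blood_change_pct: float
    dermal_thickness_cm: float
    artery_depth_cm: float

    def __post_init__(self) -> None:
        for name in ("bmi", "tewl_pct", "blood_change_pct", "dermal_thickness_cm", "artery_depth_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: The five BMI levels of the obesity parameter table (thickness/depth in cm).
DEFAULT_SCENARIOS: tuple[ObesityScenario, ...] = (
    ObesityScenario(25, 0, 0, 0.10, 0.25),
    ObesityScenario(30, 30, 10, 0.1325, 0.275),
    ObesityScenario(35, 40, 20, 0.175, 0.30),
    ObesityScenario(40, 50, 30, 0.2125, 0.325),
    ObesityScenario(45, 60, 40, 0.25, 0.35),
)


@dataclass(frozen=True)
class MelaninSetting:
    """Epidermal melanin volume fraction (0..0.5)."""

    melanin_volume_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.melanin_volume_fraction <= 0.5:
            raise ValueError(
                f"melanin volume fraction must lie in [0, 0.5], got {self.melanin_volume_fraction}"
            )


@dataclass(frozen=True)
class ChromophoreModel:
    """Constants of the dermal/epidermal chromophore mixtures.

    ``water_mu_a`` and ``melanin_reference_mu_a`` are compilation constants
    (inputs, not ground truth): pure-water absorption and the interior
    melanosome absorption ~519*(lambda/500 nm)^-3 cm^-1.  The residual
    (dry-matrix) and non-melanin components are calibrated at run time so the
    baseline fractions reproduce the media table exactly, whatever these
    constants are.

    ``melanin_reference_fraction`` is the volume fraction the table's
    epidermis row corresponds to.  Default 0.0: with the standard melanosome
    constant, any appreciable reference fraction would exceed the tabulated
    epidermis absorption, so the table row is treated as melanin-free.
    """

    dermis_baseline_water_fraction: float = 0.65
    dermis_baseline_blood_fraction: float = 0.02
    water_mu_a: Mapping[int, float] = field(
        default_factory=lambda: {660: 0.0036, 890: 0.0617}
    )
    melanin_reference_mu_a: Mapping[int, float] = field(
        default_factory=lambda: {660: 225.7, 890: 92.0}
    )
    melanin_reference_fraction: float = 0.0

    def dermis_residual_mu_a(self, wavelength: int, table: MediumTable) -> float:
        """Dry-matrix absorption calibrated to reproduce the dermis row."""
        base = table.get("dermis", wavelength).mu_a
        blood = table.get("blood", wavelength).mu_a
        residual = (
            base
            - self.dermis_baseline_blood_fraction * blood
            - self.dermis_baseline_water_fraction * self.water_mu_a[wavelength]
        )
        if residual < 0:
            raise ValueError(
                "calibrated dermis residual absorption is negative; baseline "
                "fractions are inconsistent with the media table"
            )
        return residual

    def non_melanin_mu_a(self, wavelength: int, table: MediumTable) -> float:
        """Non-melanin epidermis absorption calibrated at the reference fraction."""
        m_ref = self.melanin_reference_fraction
        base = table.get("epidermis", wavelength).mu_a
        value = (base - m_ref * self.melanin_reference_mu_a[wavelength]) / (1.0 - m_ref)
        if value < 0:
            raise ValueError(
                "calibrated non-melanin epidermis absorption is negative; lower "
                "melanin_reference_fraction or the melanin reference spectrum"
            )
        return value


def baseline_properties(medium: str, wavelength: int, table: MediumTable | None = None) -> OpticalProperties:
    """Unmodified properties of ``medium`` at ``wavelength`` (table lookup)."""
    return (table or MediumTable()).get(medium, wavelength)


def scale_thin_layer(
    props: OpticalProperties, true_thickness_cm: float, voxel_thickness_cm: float
) -> OpticalProperties:
    """Rescale a thin layer's coefficients to preserve its optical thickness.

    A layer thinner than one voxel is realized as a full voxel whose mu_a and
    mu_s are multiplied by ``true_thickness / voxel_thickness`` so the
    products mu*t are conserved.  g and n are unchanged.
    """
    if true_thickness_cm <= 0 or voxel_thickness_cm <= 0:
        raise ValueError("layer thicknesses must be positive")
    ratio = true_thickness_cm / voxel_thickness_cm
    return OpticalProperties(props.mu_a * ratio, props.mu_s * ratio, props.g, props.n)


def dermis_adjusted_mu_a(
    wavelength: int,
    scenario: ObesityScenario,
    model: ChromophoreModel | None = None,
    table: MediumTable | None = None,
) -> float:
    """Dermis absorption under the scenario's water-loss/perfusion changes.

    W = W0*(1 - tewl/100), B = B0*(1 + blood_change/100);
    mu_a = B*mu_a_blood + W*mu_a_water + residual.
    """
    model = model or ChromophoreModel()
    table = table or MediumTable()
    water = model.dermis_baseline_water_fraction * (1.0 - scenario.tewl_pct / 100.0)
    blood = model.dermis_baseline_blood_fraction * (1.0 + scenario.blood_change_pct / 100.0)
    if not (0.0 <= water <= 1.0 and 0.0 <= blood <= 1.0):
        raise ValueError(
            f"composed dermal fractions outside [0, 1]: water={water}, blood={blood}"
        )
    return (
        blood * table.get("blood", wavelength).mu_a
        + water * model.water_mu_a[wavelength]
        + model.dermis_residual_mu_a(wavelength, table)
    )


def epidermis_melanin_mu_a(
    wavelength: int,
    setting: MelaninSetting,
    model: ChromophoreModel | None = None,
    table: MediumTable | None = None,
) -> float:
    """Epidermis absorption at the given melanin volume fraction.

    mu_a = M*mu_a_melanin + (1 - M)*mu_a_non_melanin, with the non-melanin
    component calibrated so the reference fraction reproduces the table row.
    """
    model = model or ChromophoreModel()
    table = table or MediumTable()
    m = setting.melanin_volume_fraction
    return m * model.melanin_reference_mu_a[wavelength] + (1.0 - m) * model.non_melanin_mu_a(
        wavelength, table
    )
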