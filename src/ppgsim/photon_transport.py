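"""Weighted-photon voxel Monte Carlo transport and NA-limited detection.

`run_simulation` drives the compiled kernel in :mod:`ppgsim._kernel` over a
labeled :class:`~ppgsim.tissue_volume.VoxelGrid`.  The module also exposes
the individual physics primitives (beam launch, free-path sampling,
Beer-Lambert deposition, Henyey-Greenstein deflection, Fresnel interfaces,
Russian roulette, detector acceptance) as plain functions so each can be
validated against its closed form in isolation.

Seeding is per photon index (common random numbers): two runs with the same
base seed use identical photon substreams regardless of geometry, so
partitioned runs merge exactly and geometry sweeps are positively
correlated, which sharply reduces the variance of waveform *differences*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as _k
from ._kernel import transport_kernel
from .grid import GridSpec
from .tissue_volume import VoxelGrid

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "PhotonState",
    "SimResult",
    "launch_photon",
    "sample_step",
    "move_and_deposit",
    "sample_hg_scatter",
    "fresnel_interface",
    "roulette",
    "detect_exit",
    "run_simulation",
    "compute_weight_windows",
]


@dataclass(frozen=True)
class SourceSpec:
    """Surface illumination spot: position, waist and profile.

    ``beam_waist_radius_cm`` is the 1/e^2 intensity radius for the (default)
    gaussian profile, or the disc radius for the flat profile.  The beam
    enters normally (+z).
    """

    beam_waist_radius_cm: float = 0.06
    x_cm: float = 0.0
    y_cm: float = -0.485
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if self.beam_waist_radius_cm <= 0:
            raise ValueError("beam waist radius must be positive")
        if self.profile not in ("gaussian", "flat"):
            raise ValueError("profile must be 'gaussian' or 'flat'")


@dataclass(frozen=True)
class DetectorSpec:
    """Square collection aperture on the surface with an NA acceptance cone.

    Default geometry centers the source-detector pair on the grid with a
    0.97 cm separation along +y (along the artery), a 0.35 cm square
    aperture (0.1225 cm^2) and NA 0.866 (60 deg half-angle in air).
    """

    x_cm: float = 0.0
    y_cm: float = 0.485
    aperture_side_cm: float = 0.35
    numerical_aperture: float = 0.866

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture <= 1.0:
            raise ValueError("numerical aperture must lie in (0, 1]")
        if self.aperture_side_cm <= 0:
            raise ValueError("aperture side must be positive")

    @property
    def cos_acceptance(self) -> float:
        return float(np.sqrt(1.0 - self.numerical_aperture**2))

    @classmethod
    def paired_with_source(
        cls, separation_cm: float = 0.97, **kwargs
    ) -> tuple[SourceSpec, "DetectorSpec"]:
        """Source/detector pair centered on the grid along +y."""
        half = separation_cm / 2.0
        return SourceSpec(y_cm=-half), cls(y_cm=half, **kwargs)


@dataclass
class PhotonState:
    """Plumbing record for a single photon packet."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    alive: bool = True

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


@dataclass(frozen=True)
class SimResult:
    """Normalized tallies of one transport run (fractions of launched weight)."""

    detected_weight_fraction: float
    total_diffuse_reflectance: float
    specular_reflectance: float
    absorbed_fraction: float
    transmitted_fraction: float
    side_escape_fraction: float
    roulette_residual: float
    n_photons: int
    seed: int
    absorption_map: np.ndarray | None = None

    @property
    def conservation_residual(self) -> float:
        """(all tallies + roulette net) - 1; ~1e-12 per run."""
        return (
            self.specular_reflectance
            + self.total_diffuse_reflectance
            + self.absorbed_fraction
            + self.transmitted_fraction
            + self.side_escape_fraction
            + self.roulette_residual
            - 1.0
        )

    def merged_with(self, other: "SimResult") -> "SimResult":
        """Weight-average of two partitioned runs of the same configuration."""
        n = self.n_photons + other.n_photons
        f = lambda a, b: (a * self.n_photons + b * other.n_photons) / n
        amap = None
        if self.absorption_map is not None and other.absorption_map is not None:
            amap = self.absorption_map + other.absorption_map
        return SimResult(
            f(self.detected_weight_fraction, other.detected_weight_fraction),
            f(self.total_diffuse_reflectance, other.total_diffuse_reflectance),
            f(self.specular_reflectance, other.specular_reflectance),
            f(self.absorbed_fraction, other.absorbed_fraction),
            f(self.transmitted_fraction, other.transmitted_fraction),
            f(self.side_escape_fraction, other.side_escape_fraction),
            f(self.roulette_residual, other.roulette_residual),
            n,
            self.seed,
            amap,
        )


# ---------------------------------------------------------------------------
# physics primitives (unit-testable forms of what the kernel does inline)
# ---------------------------------------------------------------------------

def launch_photon(source: SourceSpec, rng: np.random.Generator, n_tissue: float = 1.47,
                  n_ambient: float = 1.0) -> PhotonState:
    """Sample a surface entry point from the beam profile, pointing +z.

    The launched weight is 1 minus the normal-incidence specular reflection
    at the ambient-tissue interface (tallied separately by the kernel).
    """
    u1, u2 = rng.random(2)
    if source.profile == "gaussian":
        r = source.beam_waist_radius_cm * np.sqrt(-np.log(1.0 - u1) / 2.0)
    else:
        r = source.beam_waist_radius_cm * np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    pos = np.array([source.x_cm + r * np.cos(phi), source.y_cm + r * np.sin(phi), 0.0])
    r_spec, _ = _k._fresnel_unpolarized(n_ambient, n_tissue, 1.0)
    return PhotonState(pos, np.array([0.0, 0.0, 1.0]), 1.0 - r_spec)


def sample_step(mu_t: float, rng: np.random.Generator) -> float:
    """Exponential free path: s = -ln(xi)/mu_t with xi in (0, 1]."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    xi = 1.0 - rng.random()  # (0, 1]
    return -np.log(xi) / mu_t


def move_and_deposit(
    photon: PhotonState, mu_a_segments: np.ndarray, lengths: np.ndarray,
    deposit_into: np.ndarray | None = None,
) -> PhotonState:
    """Advance a photon through voxel segments with Beer-Lambert weighting.

    For each traversed segment of length l in a voxel with absorption mu_a
    the deposited weight is w*(1 - exp(-mu_a*l)); the survivor continues.
    """
    if not photon.alive:
        raise ValueError("photon is not alive")
    w = photon.weight
    pos = photon.position.copy()
    for i, (mu_a, length) in enumerate(zip(np.atleast_1d(mu_a_segments), np.atleast_1d(lengths))):
        att = np.exp(-mu_a * length)
        if deposit_into is not None:
            deposit_into[i] += w * (1.0 - att)
        w *= att
        pos += photon.direction * length
    return PhotonState(pos, photon.direction, w)


def sample_hg_scatter(g: float, rng: np.random.Generator,
                      direction: np.ndarray | None = None) -> np.ndarray:
    """New unit direction after a Henyey-Greenstein deflection about ``direction``."""
    if abs(g) >= 1.0:
        raise ValueError("anisotropy must satisfy |g| < 1")
    if direction is None:
        direction = np.array([0.0, 0.0, 1.0])
    cost = _k._hg_cos(g, 1.0 - rng.random())
    phi = 2.0 * np.pi * rng.random()
    return np.array(_k._spin(direction[0], direction[1], direction[2], cost, phi))


def fresnel_interface(
    direction: np.ndarray, n1: float, n2: float, normal: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Reflect (probability R, or always under TIR) or refract by Snell's law.

    Returns (new unit direction, reflected?).  ``normal`` must be a unit
    vector pointing from medium 1 into medium 2.
    """
    direction = np.asarray(direction, float)
    normal = np.asarray(normal, float)
    cosi = float(np.dot(direction, normal))
    if cosi <= 0:
        raise ValueError("direction must point from medium 1 into medium 2")
    r, cost = _k._fresnel_unpolarized(n1, n2, cosi)
    if rng.random() < r:
        return direction - 2.0 * cosi * normal, True
    ratio = n1 / n2
    tangential = direction - cosi * normal
    out = tangential * ratio + cost * normal
    return out / np.linalg.norm(out), False


def roulette(
    photon: PhotonState, threshold: float, survival_multiplier: float,
    rng: np.random.Generator,
) -> PhotonState:
    """Unbiased Russian-roulette termination of low-weight packets."""
    if photon.weight >= threshold or survival_multiplier <= 1.0:
        return photon
    if rng.random() <= 1.0 / survival_multiplier:
        return PhotonState(photon.position, photon.direction,
                           min(1.0, photon.weight * survival_multiplier))
    dead = PhotonState(photon.position, photon.direction, 0.0)
    dead.alive = False
    return dead


def detect_exit(
    exit_xy: tuple[float, float], ambient_cos_theta: float, detector: DetectorSpec
) -> bool:
    """Acceptance test for a photon exiting the top surface into ambient."""
    x, y = exit_xy
    return (
        abs(x - detector.x_cm) <= detector.aperture_side_cm / 2.0
        and abs(y - detector.y_cm) <= detector.aperture_side_cm / 2.0
        and ambient_cos_theta >= detector.cos_acceptance
    )


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def run_simulation(
    volume: VoxelGrid,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    *,
    photon_offset: int = 0,
    roulette_threshold: float = 1e-4,
    roulette_multiplier: float = 10.0,
    internal_fresnel: bool = True,
    ambient_n: float = 1.0,
    accumulate_map: bool = False,
    detection_estimator: str = "shadow_ray",
    weight_window_map: np.ndarray | None = None,
) -> SimResult:
    """Transport ``n_photons`` through ``volume`` and tally the outcome.

    Deterministic for a given (seed, photon_offset): photon ``i`` uses the
    substream keyed by ``photon_offset + i``, so two runs with offsets
    [0, n) and [n, 2n) merge to exactly the [0, 2n) single run.

    ``detection_estimator``: ``"shadow_ray"`` (default) scores the expected
    uncollided escape into the detector at every scattering event (next-event
    estimation — unbiased, far lower variance for this small aperture);
    ``"analog"`` tallies only photons that physically exit through the
    aperture inside the acceptance cone.

    ``weight_window_map``: optional coarse (supervoxel) target-weight map
    from :func:`compute_weight_windows`; photons split above the window and
    play roulette below it, concentrating the population on detector-bound
    paths.  Unbiased; changes only the variance.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if detection_estimator not in ("shadow_ray", "analog"):
        raise ValueError("detection_estimator must be 'shadow_ray' or 'analog'")
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    g = volume.grid
    props = volume.properties
    if accumulate_map:
        abs_map = np.zeros(volume.media.shape)
    else:
        abs_map = np.zeros((1, 1, 1))
    if weight_window_map is None:
        ww = np.ones((1, 1, 1))
        use_ww = False
    else:
        ww = np.ascontiguousarray(weight_window_map, dtype=np.float64)
        use_ww = True
    tallies = transport_kernel(
        volume.media,
        np.ascontiguousarray(props[:, 0]),
        np.ascontiguousarray(props[:, 1]),
        np.ascontiguousarray(props[:, 2]),
        np.ascontiguousarray(props[:, 3]),
        g.dx, g.dy, g.dz,
        -g.lx_cm / 2.0, -g.ly_cm / 2.0,
        source.x_cm, source.y_cm, source.beam_waist_radius_cm,
        source.profile == "gaussian",
        ambient_n,
        detector.x_cm, detector.y_cm, detector.aperture_side_cm / 2.0,
        detector.cos_acceptance, detector.numerical_aperture,
        n_photons, photon_offset, np.uint64(seed),
        roulette_threshold, roulette_multiplier,
        internal_fresnel, detection_estimator == "shadow_ray",
        abs_map, accumulate_map,
        np.zeros((1, 1, 1)), False,
        ww, use_ww,
    )
    t = tallies / n_photons
    return SimResult(
        detected_weight_fraction=float(t[_k.TALLY_DETECTED]),
        total_diffuse_reflectance=float(t[_k.TALLY_DIFFUSE]),
        specular_reflectance=float(t[_k.TALLY_SPECULAR]),
        absorbed_fraction=float(t[_k.TALLY_ABSORBED]),
        transmitted_fraction=float(t[_k.TALLY_TRANSMITTED]),
        side_escape_fraction=float(t[_k.TALLY_SIDE]),
        roulette_residual=float(t[_k.TALLY_ROULETTE_LOSS] - t[_k.TALLY_ROULETTE_GAIN]),
        n_photons=n_photons,
        seed=seed,
        absorption_map=abs_map if accumulate_map else None,
    )


def compute_weight_windows(
    volume: VoxelGrid,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    n_photons: int = 30_000,
    seed: int = 0,
    *,
    supervoxel: tuple[int, int, int] | int = 8,
    max_boost: float = 4096.0,
    max_suppress: float = 256.0,
) -> np.ndarray:
    """Coarse target-weight map for importance splitting, from an adjoint run.

    Launches photons from the detector position (flat disc of the aperture
    area) and tallies the collision weight density on a supervoxel mesh; this
    density is proportional to the detector importance of each region.  The
    returned target weight is I(source)/I(r), clipped to
    [1/max_boost, max_suppress]: photons heading into high-importance regions
    split (down to ~1/max_boost of their weight), photons wandering into
    regions the detector cannot see are rouletted away.

    The map only shapes variance, never the expectation, so one map (usually
    built on the undilated baseline volume) can serve a whole sweep — which
    also preserves common random numbers across the swept geometries.
    """
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    if isinstance(supervoxel, int):
        supervoxel = (supervoxel, supervoxel, supervoxel)
    sx, sy, sz = supervoxel
    g = volume.grid
    shape = (
        (g.nx + sx - 1) // sx,
        (g.ny + sy - 1) // sy,
        (g.nz + sz - 1) // sz,
    )
    imp = np.zeros(shape)
    props = volume.properties
    adjoint_radius = detector.aperture_side_cm / np.sqrt(np.pi)  # area-equivalent
    transport_kernel(
        volume.media,
        np.ascontiguousarray(props[:, 0]),
        np.ascontiguousarray(props[:, 1]),
        np.ascontiguousarray(props[:, 2]),
        np.ascontiguousarray(props[:, 3]),
        g.dx, g.dy, g.dz,
        -g.lx_cm / 2.0, -g.ly_cm / 2.0,
        detector.x_cm, detector.y_cm, adjoint_radius, False,
        1.0,
        detector.x_cm, detector.y_cm, detector.aperture_side_cm / 2.0,
        detector.cos_acceptance, detector.numerical_aperture,
        n_photons, 0, np.uint64(seed),
        1e-4, 10.0,
        True, False,
        np.zeros((1, 1, 1)), False,
        imp, True,
        np.ones((1, 1, 1)), False,
    )
    floor = imp[imp > 0].min() if (imp > 0).any() else 1.0
    imp = np.maximum(imp, floor / 10.0)
    fx = (g.nx + shape[0] - 1) // shape[0]
    fy = (g.ny + shape[1] - 1) // shape[1]
    src_ix = int((source.x_cm + g.lx_cm / 2.0) / g.dx) // fx
    src_iy = int((source.y_cm + g.ly_cm / 2.0) / g.dy) // fy
    i_src = imp[src_ix, src_iy, 0]
    target = np.clip(i_src / imp, 1.0 / max_boost, max_suppress)
    return target
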