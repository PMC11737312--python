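"""Static jaw-lever bite-force model from in-situ muscle measurements.

The jaw is treated as a static third-class lever viewed laterally in 2D.
For each jaw muscle measured in situ (wet mass, projected surface area,
pennation angle, line-of-action angle, three moment-arm lengths) the chain is

    volume    V = m / rho                      (rho = muscle tissue density)
    thickness T = V / A                        (A = lens-corrected area)
    fascicle  l = T / sin(alpha)               (alpha = 45 deg projection)
    PCSA        = m cos(theta) / (rho l)       (theta = pennation angle)
    force     F = sigma * PCSA                 (sigma = tetanic stress)
    torque  Tau = r * F * sin(phi)             (r = mean moment arm,
                                                phi = line-of-action angle)

Adductor torques are summed, divided by the out-lever moment arm and doubled
for the two sides of the jaw to give the whole-head bite force in newtons.
Abductors (the m. depressor mandibulae) are carried through the chain for
reporting but contribute nothing to the closing force.

Because the fascicle length is itself derived from the same mass via V and T,
mass and density cancel algebraically and PCSA reduces to
``A * sin(alpha) * cos(theta)``; this identity is exploited both as a test
invariant and by the synthetic-data generator to invert the model exactly.

Units are grams, millimetres and radians throughout; forces come out in
newtons because the tetanic stress is given in N/mm^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "InvalidMeasurementError",
    "ModelConstants",
    "MuscleObservation",
    "JawGeometry",
    "SpecimenRecord",
    "MuscleDerived",
    "BiteForceResult",
    "ADDUCTOR",
    "ABDUCTOR",
    "scale_factor",
    "correct_area",
    "muscle_volume",
    "muscle_thickness",
    "fascicle_length",
    "pcsa",
    "muscle_force",
    "mean_moment_arm",
    "muscle_torque",
    "derive_muscle",
    "bite_force",
]

ADDUCTOR = "adductor"
ABDUCTOR = "abductor"

#: g/mm^3; the standard wet skeletal-muscle tissue density (1.06 g/cm^3).
MUSCLE_DENSITY_G_PER_MM3 = 1.06e-3
#: N/mm^2; common estimate of maximal tetanic stress of vertebrate muscle.
TETANIC_STRESS_N_PER_MM2 = 0.3


class InvalidMeasurementError(ValueError):
    """A dissection measurement violates its physical domain."""


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants and switches of the PCSA-lever model.

    Parameters
    ----------
    muscle_density : float
        Muscle tissue density in g/mm^3 (default 1.06e-3, i.e. 1.06 g/cm^3).
    tetanic_stress : float
        Maximal isometric stress in N/mm^2 (default 0.3).
    fascicle_angle : float
        Angle in radians at which fascicles rise from the bone, used to
        project muscle thickness into fascicle length (default pi/4).
    bilateral_factor : float
        Multiplier converting one-side torque into whole-jaw force; 2 for
        a bilaterally symmetric jaw, 1 to report a single side.
    area_scale_power : int
        Power applied to the linear lens-compression scale factor when
        correcting areas; 2 (default) treats the factor as linear so that
        an areal quantity is corrected twice, 1 applies it once.
    """

    muscle_density: float = MUSCLE_DENSITY_G_PER_MM3
    tetanic_stress: float = TETANIC_STRESS_N_PER_MM2
    fascicle_angle: float = math.pi / 4
    bilateral_factor: float = 2
    area_scale_power: int = 2

    def __post_init__(self) -> None:
        if self.muscle_density <= 0:
            raise InvalidMeasurementError("muscle_density must be > 0")
        if self.tetanic_stress <= 0:
            raise InvalidMeasurementError("tetanic_stress must be > 0")
        if not 0 < self.fascicle_angle <= math.pi / 2:
            raise InvalidMeasurementError("fascicle_angle must be in (0, pi/2]")
        if self.bilateral_factor not in (1, 2):
            raise InvalidMeasurementError("bilateral_factor must be 1 or 2")
        if self.area_scale_power not in (1, 2):
            raise InvalidMeasurementError("area_scale_power must be 1 or 2")


@dataclass(frozen=True)
class MuscleObservation:
    """Raw dissection measurements for one jaw muscle.

    ``surface_area`` is the digital (image-derived) area before the
    lens-compression correction. ``area_is_proxy`` flags muscles whose area
    was substituted by a bony proxy (the palatine bone for the
    m. pterygoideus dorsalis, whose body is not fully visible laterally).
    """

    name: str
    role: str
    wet_mass: float          # g
    surface_area: float      # mm^2, digital, pre-correction
    pennation_angle: float   # rad
    loa_angle: float         # rad, line of action to the defined horizontal
    moment_arms: tuple[float, float, float]  # mm, start/mid/end of the LOA
    area_is_proxy: bool = False

    def __post_init__(self) -> None:
        if self.role not in (ADDUCTOR, ABDUCTOR):
            raise InvalidMeasurementError(
                f"muscle {self.name!r}: role must be {ADDUCTOR!r} or {ABDUCTOR!r}"
            )
        if self.wet_mass < 0:
            raise InvalidMeasurementError(f"muscle {self.name!r}: wet_mass < 0")
        if self.surface_area <= 0:
            raise InvalidMeasurementError(f"muscle {self.name!r}: surface_area <= 0")
        if not 0 <= self.pennation_angle < math.pi / 2:
            raise InvalidMeasurementError(
                f"muscle {self.name!r}: pennation_angle outside [0, pi/2)"
            )
        if not 0 <= self.loa_angle <= math.pi:
            raise InvalidMeasurementError(
                f"muscle {self.name!r}: loa_angle outside [0, pi]"
            )
        arms = tuple(float(a) for a in self.moment_arms)
        if len(arms) != 3:
            raise InvalidMeasurementError(
                f"muscle {self.name!r}: exactly three moment arms required"
            )
        if any(a < 0 for a in arms):
            raise InvalidMeasurementError(f"muscle {self.name!r}: moment arm < 0")
        object.__setattr__(self, "moment_arms", arms)


@dataclass(frozen=True)
class JawGeometry:
    """Lever geometry of one specimen.

    ``out_lever`` is the perpendicular distance from the quadrate fulcrum to
    the bite point. The two reference distances are the same two-landmark
    span measured physically with callipers and digitally on the image; their
    ratio corrects the lens compression of the photographs.
    """

    out_lever: float               # mm
    physical_ref_distance: float   # mm
    digital_ref_distance: float    # mm

    def __post_init__(self) -> None:
        if self.out_lever <= 0:
            raise InvalidMeasurementError("out_lever must be > 0")
        if self.physical_ref_distance <= 0 or self.digital_ref_distance <= 0:
            raise InvalidMeasurementError("reference distances must be > 0")


@dataclass(frozen=True)
class SpecimenRecord:
    """One dissected head: geometry plus its list of measured muscles."""

    specimen_id: str
    species: str
    geometry: JawGeometry
    muscles: tuple[MuscleObservation, ...]
    constants: ModelConstants = field(default_factory=ModelConstants)
    side: str = "mean"

    def __post_init__(self) -> None:
        object.__setattr__(self, "muscles", tuple(self.muscles))
        if self.side not in ("left", "right", "mean"):
            raise InvalidMeasurementError("side must be left, right or mean")
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise InvalidMeasurementError(
                f"specimen {self.specimen_id!r}: duplicate muscle names"
            )

    @property
    def adductors(self) -> tuple[MuscleObservation, ...]:
        return tuple(m for m in self.muscles if m.role == ADDUCTOR)


@dataclass(frozen=True)
class MuscleDerived:
    """Derived quantities for one muscle (all non-negative)."""

    name: str
    role: str
    corrected_area: float   # mm^2
    volume: float           # mm^3
    thickness: float        # mm
    fascicle_length: float  # mm
    pcsa: float             # mm^2
    force: float            # N
    mean_moment_arm: float  # mm
    torque: float           # N*mm
    area_is_proxy: bool = False
    contributes: bool = True


@dataclass(frozen=True)
class BiteForceResult:
    """Whole-jaw bite force with the per-muscle breakdown."""

    specimen_id: str
    species: str
    bite_force: float  # N
    muscles: tuple[MuscleDerived, ...]
    warnings: tuple[str, ...] = ()


def scale_factor(physical_ref_distance: float, digital_ref_distance: float) -> float:
    """Linear lens-compression correction: physical over digital distance."""
    if physical_ref_distance <= 0 or digital_ref_distance <= 0:
        raise InvalidMeasurementError("reference distances must be > 0")
    return physical_ref_distance / digital_ref_distance


def correct_area(surface_area: float, factor: float, power: int = 2) -> float:
    """Apply the linear scale factor to an area (squared by default)."""
    if surface_area <= 0:
        raise InvalidMeasurementError("surface_area must be > 0")
    if factor <= 0:
        raise InvalidMeasurementError("scale factor must be > 0")
    return surface_area * factor**power


def muscle_volume(wet_mass: float, density: float = MUSCLE_DENSITY_G_PER_MM3) -> float:
    """V = m / rho, in mm^3 for mass in g and density in g/mm^3."""
    if wet_mass < 0:
        raise InvalidMeasurementError("wet_mass must be >= 0")
    if density <= 0:
        raise InvalidMeasurementError("density must be > 0")
    return wet_mass / density


def muscle_thickness(volume: float, corrected_area: float) -> float:
    """T = V / A: thickness of the muscle sheet if projected off the bone."""
    if corrected_area <= 0:
        raise InvalidMeasurementError("corrected_area must be > 0")
    if volume < 0:
        raise InvalidMeasurementError("volume must be >= 0")
    return volume / corrected_area


def fascicle_length(thickness: float, fascicle_angle: float = math.pi / 4) -> float:
    """l = T / sin(alpha): thickness projected along fascicles at ``alpha``."""
    if not 0 < fascicle_angle <= math.pi / 2:
        raise InvalidMeasurementError("fascicle_angle must be in (0, pi/2]")
    if thickness < 0:
        raise InvalidMeasurementError("thickness must be >= 0")
    return thickness / math.sin(fascicle_angle)


def pcsa(
    wet_mass: float,
    pennation_angle: float,
    density: float,
    fascicle_len: float,
) -> float:
    """Physiological cross-sectional area, m cos(theta) / (rho l), in mm^2."""
    if fascicle_len <= 0:
        raise InvalidMeasurementError("fascicle length must be > 0")
    if wet_mass < 0:
        raise InvalidMeasurementError("wet_mass must be >= 0")
    if density <= 0:
        raise InvalidMeasurementError("density must be > 0")
    if not 0 <= pennation_angle <= math.pi / 2:
        raise InvalidMeasurementError("pennation_angle outside [0, pi/2]")
    return wet_mass * math.cos(pennation_angle) / (density * fascicle_len)


def muscle_force(pcsa_mm2: float, tetanic_stress: float = TETANIC_STRESS_N_PER_MM2) -> float:
    """F = sigma * PCSA, in N."""
    if pcsa_mm2 < 0:
        raise InvalidMeasurementError("pcsa must be >= 0")
    if tetanic_stress <= 0:
        raise InvalidMeasurementError("tetanic_stress must be > 0")
    return tetanic_stress * pcsa_mm2


def mean_moment_arm(moment_arms) -> float:
    """Arithmetic mean of the start/mid/end orthogonal moment arms."""
    arms = tuple(float(a) for a in moment_arms)
    if len(arms) != 3:
        raise InvalidMeasurementError("exactly three moment arms required")
    if any(a < 0 for a in arms):
        raise InvalidMeasurementError("moment arms must be >= 0")
    return sum(arms) / 3.0


def muscle_torque(mean_arm: float, force: float, loa_angle: float) -> float:
    """Tau = r F sin(phi), in N*mm."""
    if mean_arm < 0 or force < 0:
        raise InvalidMeasurementError("moment arm and force must be >= 0")
    if not 0 <= loa_angle <= math.pi:
        raise InvalidMeasurementError("loa_angle outside [0, pi]")
    return mean_arm * force * math.sin(loa_angle)


def derive_muscle(
    obs: MuscleObservation,
    geometry: JawGeometry,
    constants: ModelConstants | None = None,
) -> MuscleDerived:
    """Run the full per-muscle chain from raw measurements to torque."""
    c = constants or ModelConstants()
    k = scale_factor(geometry.physical_ref_distance, geometry.digital_ref_distance)
    area = correct_area(obs.surface_area, k, c.area_scale_power)
    vol = muscle_volume(obs.wet_mass, c.muscle_density)
    thick = muscle_thickness(vol, area)
    fasc = fascicle_length(thick, c.fascicle_angle)
    if fasc > 0:
        area_pcsa = pcsa(obs.wet_mass, obs.pennation_angle, c.muscle_density, fasc)
    else:
        area_pcsa = 0.0  # massless muscle: no fascicle, no force
    force = muscle_force(area_pcsa, c.tetanic_stress)
    arm = mean_moment_arm(obs.moment_arms)
    torque = muscle_torque(arm, force, obs.loa_angle)
    return MuscleDerived(
        name=obs.name,
        role=obs.role,
        corrected_area=area,
        volume=vol,
        thickness=thick,
        fascicle_length=fasc,
        pcsa=area_pcsa,
        force=force,
        mean_moment_arm=arm,
        torque=torque,
        area_is_proxy=obs.area_is_proxy,
        contributes=obs.role == ADDUCTOR,
    )


def bite_force(specimen: SpecimenRecord) -> BiteForceResult:
    """Whole-jaw bite force of a specimen.

    Sums the torques of the adductor muscles, divides by the out-lever and
    multiplies by the bilateral factor. Abductors appear in the breakdown
    with ``contributes=False``. A specimen without adductors yields 0 N and
    a warning record.
    """
    derived = tuple(
        derive_muscle(m, specimen.geometry, specimen.constants)
        for m in specimen.muscles
    )
    notes: list[str] = []
    adductor_torque = sum(d.torque for d in derived if d.contributes)
    if not any(d.contributes for d in derived):
        msg = f"specimen {specimen.specimen_id!r}: no adductor muscles; bite force is 0"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    if any(d.area_is_proxy for d in derived):
        notes.append(
            "one or more muscle areas are bony proxies (palatine substitution)"
        )
    bf = (
        specimen.constants.bilateral_factor
        * adductor_torque
        / specimen.geometry.out_lever
    )
    return BiteForceResult(
        specimen_id=specimen.specimen_id,
        species=specimen.species,
        bite_force=bf,
        muscles=derived,
        warnings=tuple(notes),
    )


def with_constants(specimen: SpecimenRecord, **overrides) -> SpecimenRecord:
    """Return a copy of ``specimen`` with some model constants replaced."""
    return replace(specimen, constants=replace(specimen.constants, **overrides))
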