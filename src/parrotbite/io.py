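"""CSV / Newick / YAML input-output with row-level validation.

All on-disk angle columns are degrees (``*_deg``); they are converted to
radians at the I/O boundary and everything downstream works in radians.
Species labels are normalized (spaces to underscores) only at this boundary.
Row-level problems are aggregated into a single :class:`ValidationError`
listing every offending row rather than failing on the first.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import biomech
from .biomech import (
    BiteForceResult,
    JawGeometry,
    ModelConstants,
    MuscleObservation,
    SpecimenRecord,
)

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_traits",
    "read_muscles",
    "read_geometry",
    "read_newick",
    "write_newick",
    "specimens_from_tables",
    "results_to_frame",
    "write_bite_forces",
    "file_digest",
]

logger = logging.getLogger(__name__)

MUSCLE_COLUMNS = [
    "specimen_id",
    "species",
    "side",
    "muscle",
    "role",
    "wet_mass_g",
    "surface_area_mm2",
    "pennation_deg",
    "loa_deg",
    "arm1_mm",
    "arm2_mm",
    "arm3_mm",
    "area_is_proxy",
]
GEOMETRY_COLUMNS = ["specimen_id", "out_lever_mm", "physical_ref_mm", "digital_ref_mm"]
TRAIT_REQUIRED = ["species"]


class ValidationError(ValueError):
    """Input validation failed; carries one message per offending row."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "input validation failed:\n  " + "\n  ".join(self.problems)
        )


@dataclass
class RunConfig:
    """Run-level configuration, typically loaded from YAML.

    Unknown keys are rejected so typos do not silently fall back to
    defaults.
    """

    muscle_density: float = biomech.MUSCLE_DENSITY_G_PER_MM3
    tetanic_stress: float = biomech.TETANIC_STRESS_N_PER_MM2
    fascicle_angle_deg: float = 45.0
    bilateral_factor: float = 2
    area_scale_power: int = 2
    angle_units: str = "degrees"
    lambda_mode: str = "ML"          # "ML" or a number in [0, 1]
    isometric_exponents: dict = field(
        default_factory=lambda: {
            "force~mass": 0.66,
            "force~length": 2.0,
            "force~scar_length": 2.0,
        }
    )
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError([f"{path}: config must be a mapping"])
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(
                [f"{path}: unknown config key {k!r}" for k in unknown]
            )
        cfg = cls(**raw)
        cfg.constants()  # validate the physical constants eagerly
        if cfg.angle_units not in ("degrees", "radians"):
            raise ValidationError([f"angle_units must be degrees or radians"])
        return cfg

    def constants(self) -> ModelConstants:
        return ModelConstants(
            muscle_density=self.muscle_density,
            tetanic_stress=self.tetanic_stress,
            fascicle_angle=math.radians(self.fascicle_angle_deg),
            bilateral_factor=self.bilateral_factor,
            area_scale_power=self.area_scale_power,
        )

    def digest(self) -> str:
        payload = yaml.safe_dump(
            {f.name: getattr(self, f.name) for f in dc_fields(self)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _normalize_species_column(df: pd.DataFrame) -> pd.DataFrame:
    if "species" in df.columns:
        df = df.copy()
        df["species"] = (
            df["species"].astype(str).str.strip().str.replace(" ", "_", regex=False)
        )
    return df


def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValidationError([f"{path}: file is empty"]) from None
    if df.empty:
        raise ValidationError([f"{path}: no data rows"])
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValidationError(
            [f"{path}: missing column {c!r}" for c in missing]
        )
    return _normalize_species_column(df)


def _check_numeric(df, path, columns, positive=(), non_negative=()):
    problems = []
    for c in columns:
        vals = pd.to_numeric(df[c], errors="coerce")
        for i in df.index[vals.isna() & df[c].notna()]:
            problems.append(f"{path}: row {i}: non-numeric {c} = {df.at[i, c]!r}")
        if c in positive:
            for i in df.index[vals <= 0]:
                problems.append(f"{path}: row {i}: {c} must be > 0, got {df.at[i, c]!r}")
        if c in non_negative:
            for i in df.index[vals < 0]:
                problems.append(f"{path}: row {i}: {c} must be >= 0, got {df.at[i, c]!r}")
        df[c] = vals
    return problems


def read_traits(path) -> pd.DataFrame:
    """Species-level trait table (any subset of the trait columns)."""
    df = _read_csv(path, TRAIT_REQUIRED)
    numeric = [
        c
        for c in df.columns
        if c not in ("species", "family", "bite_force_source")
    ]
    problems = _check_numeric(df, path, numeric)
    dup = df["species"][df["species"].duplicated()]
    if "bite_force_source" not in df.columns:
        for s in dup:
            problems.append(f"{path}: duplicate species {s!r}")
    if problems:
        raise ValidationError(problems)
    return df


def read_muscles(path, angle_units: str = "degrees") -> pd.DataFrame:
    """Per-specimen x muscle dissection table; angles converted to radians
    into ``pennation_rad`` / ``loa_rad`` columns."""
    df = _read_csv(path, MUSCLE_COLUMNS[:-1])  # area_is_proxy optional
    if "area_is_proxy" not in df.columns:
        df["area_is_proxy"] = False
    problems = _check_numeric(
        df,
        path,
        ["wet_mass_g", "surface_area_mm2", "pennation_deg", "loa_deg",
         "arm1_mm", "arm2_mm", "arm3_mm"],
        positive=("surface_area_mm2",),
        non_negative=("wet_mass_g", "arm1_mm", "arm2_mm", "arm3_mm"),
    )
    dup = df.duplicated(subset=["specimen_id", "muscle"])
    for i in df.index[dup]:
        problems.append(
            f"{path}: row {i}: duplicate muscle {df.at[i, 'muscle']!r} "
            f"for specimen {df.at[i, 'specimen_id']!r}"
        )
    bad_role = ~df["role"].isin([biomech.ADDUCTOR, biomech.ABDUCTOR])
    for i in df.index[bad_role]:
        problems.append(f"{path}: row {i}: unknown role {df.at[i, 'role']!r}")
    if problems:
        raise ValidationError(problems)
    conv = math.pi / 180.0 if angle_units == "degrees" else 1.0
    df["pennation_rad"] = df["pennation_deg"] * conv
    df["loa_rad"] = df["loa_deg"] * conv
    df["area_is_proxy"] = df["area_is_proxy"].astype(bool)
    return df


def read_geometry(path) -> pd.DataFrame:
    """Per-specimen lever geometry table."""
    df = _read_csv(path, GEOMETRY_COLUMNS)
    problems = _check_numeric(
        df,
        path,
        ["out_lever_mm", "physical_ref_mm", "digital_ref_mm"],
        positive=("out_lever_mm", "physical_ref_mm", "digital_ref_mm"),
    )
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    for s in dup:
        problems.append(f"{path}: duplicate specimen_id {s!r}")
    if problems:
        raise ValidationError(problems)
    return df


def specimens_from_tables(
    muscles: pd.DataFrame,
    geometry: pd.DataFrame,
    constants: ModelConstants | None = None,
) -> list[SpecimenRecord]:
    """Join the muscle and geometry tables into specimen records."""
    constants = constants or ModelConstants()
    geo = geometry.set_index("specimen_id")
    problems = []
    records = []
    for sid, grp in muscles.groupby("specimen_id", sort=False):
        if sid not in geo.index:
            problems.append(f"specimen {sid!r} has no geometry row")
            continue
        g = geo.loc[sid]
        obs = tuple(
            MuscleObservation(
                name=r.muscle,
                role=r.role,
                wet_mass=r.wet_mass_g,
                surface_area=r.surface_area_mm2,
                pennation_angle=r.pennation_rad,
                loa_angle=r.loa_rad,
                moment_arms=(r.arm1_mm, r.arm2_mm, r.arm3_mm),
                area_is_proxy=bool(r.area_is_proxy),
            )
            for r in grp.itertuples()
        )
        side = grp["side"].iloc[0] if "side" in grp.columns else "mean"
        records.append(
            SpecimenRecord(
                specimen_id=str(sid),
                species=str(grp["species"].iloc[0]),
                side=str(side),
                geometry=JawGeometry(
                    out_lever=g.out_lever_mm,
                    physical_ref_distance=g.physical_ref_mm,
                    digital_ref_distance=g.digital_ref_mm,
                ),
                muscles=obs,
                constants=constants,
            )
        )
    if problems:
        raise ValidationError(problems)
    return records


def results_to_frame(results: list[BiteForceResult]) -> pd.DataFrame:
    """Wide per-specimen output: bite force plus the per-muscle breakdown."""
    rows = []
    for res in results:
        row = {
            "specimen_id": res.specimen_id,
            "species": res.species,
            "bite_force_N": res.bite_force,
        }
        for m in res.muscles:
            for attr in ("volume", "thickness", "fascicle_length", "pcsa",
                         "force", "torque"):
                row[f"{m.name}_{attr}"] = getattr(m, attr)
        rows.append(row)
    return pd.DataFrame(rows)


def write_bite_forces(results: list[BiteForceResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_newick(path) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring branch lengths everywhere."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError([f"{path}: Newick parse error: {exc}"]) from exc
    missing = [
        (e.head_node.taxon.label if e.head_node.taxon else "<internal>")
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None and e.length is None
    ]
    if missing:
        raise ValidationError(
            [f"{path}: edge above {m!r} lacks a branch length" for m in missing]
        )
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def file_digest(path) -> str:
    """Short SHA-256 digest of a file, for run logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
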