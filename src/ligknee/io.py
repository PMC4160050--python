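"""Plain-text readers/writers for materials, curves, corridors and reports.

Materials travel as YAML key-value files (c plus per-family a0, kappa, k1,
k2); tensile curves and kinematic traces as two-/four-column delimited
text; corridors as (abscissa, mean, ci_low, ci_high) tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import TensileCurve
from .constitutive import FiberFamily, HGOMaterial
from .knee_simulator import KinematicCurve
from .validation_metrics import Corridor

__all__ = [
    "material_to_dict",
    "material_from_dict",
    "write_material",
    "read_material",
    "write_tensile_curve",
    "read_tensile_curve",
    "write_kinematic_curve",
    "read_kinematic_curve",
    "write_corridor",
    "read_corridor",
]


def material_to_dict(mat: HGOMaterial) -> dict:
    return {
        "c": float(mat.c),
        "recruitment": mat.recruitment,
        "families": [
            {
                "a0": [float(v) for v in fam.a0],
                "kappa": float(fam.kappa),
                "k1": float(fam.k1),
                "k2": float(fam.k2),
            }
            for fam in mat.families
        ],
    }


def material_from_dict(d: dict) -> HGOMaterial:
    fams = tuple(
        FiberFamily(tuple(f["a0"]), kappa=f["kappa"], k1=f["k1"], k2=f["k2"])
        for f in d["families"]
    )
    return HGOMaterial(c=d["c"], families=fams, recruitment=d.get("recruitment", "pseudo_strain"))


def write_material(mat: HGOMaterial, path) -> None:
    Path(path).write_text(yaml.safe_dump(material_to_dict(mat), sort_keys=False))


def read_material(path) -> HGOMaterial:
    return material_from_dict(yaml.safe_load(Path(path).read_text()))


def write_tensile_curve(curve: TensileCurve, path) -> None:
    pd.DataFrame({"strain": curve.strain, "stress_MPa": curve.stress}).to_csv(path, index=False)


def read_tensile_curve(path, source_label: str | None = None) -> TensileCurve:
    df = pd.read_csv(path)
    return TensileCurve(
        strain=df.iloc[:, 0].to_numpy(),
        stress=df.iloc[:, 1].to_numpy(),
        source_label=source_label or str(path),
    )


def write_kinematic_curve(curve: KinematicCurve, path) -> None:
    pd.DataFrame(
        {
            "abscissa": curve.abscissa,
            "flexion_deg": curve.flexion,
            "abduction_deg": curve.abduction,
            "internal_rotation_deg": curve.internal_rotation,
        }
    ).to_csv(path, index=False)


def read_kinematic_curve(path, case_name: str = "", primary_angle: str = "abduction") -> KinematicCurve:
    df = pd.read_csv(path)
    return KinematicCurve(
        case_name=case_name or Path(path).stem,
        abscissa=df["abscissa"].to_numpy(),
        flexion=df["flexion_deg"].to_numpy(),
        abduction=df["abduction_deg"].to_numpy(),
        internal_rotation=df["internal_rotation_deg"].to_numpy(),
        primary_angle=primary_angle,
    )


def write_corridor(corr: Corridor, path) -> None:
    df = pd.DataFrame(
        {
            "abscissa": corr.abscissa,
            "mean": corr.mean,
            "ci_low": corr.ci_low,
            "ci_high": corr.ci_high,
        }
    )
    df.attrs["n_specimens"] = corr.n_specimens
    with open(path, "w") as fh:
        fh.write(f"# n_specimens={corr.n_specimens} angle={corr.angle} case={corr.case_name}\n")
        df.to_csv(fh, index=False)


def read_corridor(path) -> Corridor:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(tok.split("=", 1) for tok in first[1:].split())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return Corridor(
        abscissa=df["abscissa"].to_numpy(),
        mean=df["mean"].to_numpy(),
        ci_low=df["ci_low"].to_numpy(),
        ci_high=df["ci_high"].to_numpy(),
        n_specimens=int(meta.get("n_specimens", 0) or 0),
        angle=meta.get("angle", "abduction"),
        case_name=meta.get("case", ""),
    )
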