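"""Simulate the four quasi-static load cases with both ligament representations.

Builds the anatomic fiber-bundle knee model on the default geometry (using
the fitted materials from 01 when present, presets otherwise), substitutes
the uniaxial truss representation on identical attachments, and runs:
abduction ramp 0-50 N*m at 25 deg flexion; the same plus 20 N*m internal
torque; the unloaded 0-90 deg flexion sweep; and 15 N*m internal torque over
the sweep — all under 400 N quadriceps / 200 N hamstrings loads.  Writes one
kinematic trace per (case, representation) under results/curves/.

Run from the repository root:  python analysis/02_run_load_cases.py
"""

from pathlib import Path

from ligknee import build_knee_model, default_geometry, default_load_cases, run_load_case, to_uniaxial
from ligknee import io as lio

MATERIALS = Path("results/materials")
OUT = Path("results/curves")


def load_materials():
    if not MATERIALS.exists():
        return None
    mats = {p.stem: lio.read_material(p) for p in MATERIALS.glob("*.yaml")}
    return mats if len(mats) == 4 else None


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mats = load_materials()
    print("materials:", "fitted (results/materials)" if mats else "presets")
    anatomic = build_knee_model(default_geometry(), "anatomic_3d", 10, materials=mats)
    uniaxial = to_uniaxial(anatomic)
    for name, case in default_load_cases(steps=50).items():
        for tag, model in (("anatomic", anatomic), ("uniaxial", uniaxial)):
            curve = run_load_case(model, case)
            lio.write_kinematic_curve(curve, OUT / f"{name}_{tag}.csv")
            v = curve.angle_values(curve.primary_angle)
            print(f"{name:20s} {tag:9s} {curve.primary_angle:18s} "
                  f"end {v[-1]:7.2f} deg   max residual {curve.residuals.max():.1e}")
    print(f"\n8 curves written to {OUT}/ (abscissa: N*mm moment or deg flexion).")


if __name__ == "__main__":
    main()
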