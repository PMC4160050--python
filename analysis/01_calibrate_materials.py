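"""Calibrate HGO ligament materials to synthetic tensile curves.

Stands in for the study's calibration stage: for each distinct ligament
material (ACL, PCL two-family; MCL one-family; LCL copies MCL) a synthetic
uniaxial tensile curve is generated from the preset coefficients with
experimental-scale noise, then refit.  Writes the fitted materials and a
fit-quality table under results/materials/.

Run from the repository root:  python analysis/01_calibrate_materials.py
"""

from pathlib import Path

from ligknee import DEFAULT_SEED
from ligknee import io as lio
from ligknee.pipeline import calibrate_materials, default_config

OUT = Path("results/materials")


def main(seed: int = DEFAULT_SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pcfg = default_config()["pipeline"]
    fitted, table = calibrate_materials(pcfg, seed)
    for name, mat in fitted.items():
        lio.write_material(mat, OUT / f"{name}.yaml")
    table.to_csv(OUT / "calibration_fits.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nFitted materials for {sorted(fitted)} written to {OUT}/")
    print("Residual RMS is in MPa against the synthetic tensile data; the "
          "LCL row copies the MCL fit by assumption.")


if __name__ == "__main__":
    main()
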