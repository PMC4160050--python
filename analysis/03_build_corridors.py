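"""Generate the 19-virtual-specimen kinematic corridors.

Stands in for the cadaveric reference data: draws 19 perturbed anatomic
models per load case (attachment positions, material coefficients and
reference strains jittered at specimen scale), runs the case on each, and
writes the pointwise mean with its t-based 95% specimen band under
results/corridors/.

Run from the repository root:  python analysis/03_build_corridors.py
"""

from pathlib import Path

import numpy as np

from ligknee import DEFAULT_SEED, default_geometry, default_load_cases, synth_specimen_corridor
from ligknee import io as lio

OUT = Path("results/corridors")


def main(seed: int = DEFAULT_SEED) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mat_dir = Path("results/materials")
    materials = {p.stem: lio.read_material(p) for p in mat_dir.glob("*.yaml")}
    materials = materials if len(materials) == 4 else None
    print("materials:", "fitted (results/materials)" if materials else "presets")

    geometry = default_geometry()
    rng = np.random.default_rng([seed, 202])
    for name, case in default_load_cases(steps=50).items():
        corr = synth_specimen_corridor(
            geometry, case, n_specimens=19,
            seed=int(rng.integers(0, 2**31 - 1)), materials=materials,
        )
        lio.write_corridor(corr, OUT / f"{name}.csv")
        width = corr.ci_high - corr.ci_low
        print(f"{name:20s} {corr.angle:18s} band width {width.min():5.2f}-{width.max():5.2f} deg")
    print(f"\n4 corridors (n=19 each) written to {OUT}/.")


if __name__ == "__main__":
    main()
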