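"""Generators standing in for the study's unavailable inputs.

The source experiment's raw materials — digitized uniaxial tensile curves,
CT/MRI-derived joint geometry, and a 19-specimen cadaveric kinematic
corridor — are not deposited anywhere.  This module fabricates their
synthetic counterparts: smooth toe-then-linear tensile curves from a known
HGO material (so calibration can be tested as generate-and-refit), a
literature-plausible default joint geometry, and a virtual-specimen
ensemble whose pointwise mean and t-based 95% confidence band play the
role of the experimental corridor.

The corridor is generated by perturbing the *anatomic* model family
(attachment positions, material coefficients, reference strains), which by
construction makes the anatomic representation the better match — the
mechanism that lets the tests mirror the source study's qualitative
outcome without cadaver data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .calibration import TensileCurve
from .constitutive import FiberFamily, HGOMaterial, uniaxial_stress
from .errors import SolverError
from .knee_simulator import LoadCase, build_knee_model, run_load_case
from .validation_metrics import Corridor

__all__ = [
    "DEFAULT_SEED",
    "PerturbationSpec",
    "synth_tensile_curve",
    "synth_specimen_corridor",
    "default_geometry",
]

DEFAULT_SEED = 20130501


@dataclass(frozen=True)
class PerturbationSpec:
    """Specimen-to-specimen variability for the virtual-cadaver ensemble.

    material_cv : multiplicative coefficient of variation applied to
        c, k1, k2 and kappa (kappa re-clipped to [0, 1/3])
    attachment_sd_mm : isotropic Gaussian jitter of each ligament
        attachment centroid (mm)
    reference_strain_sd : additive Gaussian jitter of each ligament's
        reference (pre-)strain
    """

    material_cv: float = 0.04
    attachment_sd_mm: float = 0.5
    reference_strain_sd: float = 0.003


def synth_tensile_curve(
    true_material: HGOMaterial,
    n_points: int = 30,
    max_strain: float = 0.12,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    source_label: str = "synthetic",
) -> TensileCurve:
    """Uniaxial tensile curve from a known material, plus Gaussian noise.

    Strains are equally spaced on [0, max_strain]; stresses are the HGO
    closed form with i.i.d. additive noise (MPa), clipped at zero.
    Reproducible for a given seed.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    if max_strain <= 0.0:
        raise ValueError("max_strain must be > 0")
    if noise_sd < 0.0:
        raise ValueError("noise_sd must be >= 0")
    strain = np.linspace(0.0, max_strain, n_points)
    stress = uniaxial_stress(true_material, 1.0 + strain)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, size=n_points)
    stress = np.clip(stress, 0.0, None)
    return TensileCurve(strain=strain, stress=stress, source_label=source_label)


def _perturb_material(mat: HGOMaterial, rng: np.random.Generator, cv: float) -> HGOMaterial:
    fams = []
    for fam in mat.families:
        fams.append(
            FiberFamily(
                fam.a0,
                kappa=float(np.clip(fam.kappa * rng.lognormal(0.0, cv), 0.0, 1.0 / 3.0)),
                k1=fam.k1 * rng.lognormal(0.0, cv),
                k2=fam.k2 * rng.lognormal(0.0, cv),
            )
        )
    return replace(mat, families=tuple(fams))


def _perturb_config(cfg: dict, rng: np.random.Generator, spec: PerturbationSpec) -> dict:
    out = copy.deepcopy(cfg)
    for lig in out["ligaments"].values():
        lig["femur"] = [v + rng.normal(0.0, spec.attachment_sd_mm) for v in lig["femur"]]
        lig["tibia"] = [v + rng.normal(0.0, spec.attachment_sd_mm) for v in lig["tibia"]]
        lig["reference_strain"] = float(
            lig.get("reference_strain", 0.0) + rng.normal(0.0, spec.reference_strain_sd)
        )
    return out


def synth_specimen_corridor(
    base_config: dict,
    case: LoadCase,
    n_specimens: int = 19,
    perturbation: PerturbationSpec | None = None,
    seed: int = DEFAULT_SEED,
    n_fibers_per_bundle: int = 10,
    materials: dict[str, HGOMaterial] | None = None,
) -> Corridor:
    """Virtual-specimen kinematic corridor for one load case.

    Draws `n_specimens` perturbed anatomic models, runs the load case on
    each, and returns the pointwise mean and t-based 95% band of the
    specimen population (mean +/- t_{0.975,n-1} * sd) for the case's primary
    angle -- the degrees-wide corridor that experimental figures shade; a
    mean-CI band (sd/sqrt(n)) would be ~0.5 deg wide at n = 19 and could not
    contain any deterministic prediction with degree-scale RMSE.  A
    zero-magnitude
    perturbation collapses the band onto the base-model curve.  Any
    specimen's solver failure aborts with the specimen index named.
    """
    if n_specimens < 2:
        raise ValueError("n_specimens must be >= 2")
    spec = perturbation or PerturbationSpec()
    rng = np.random.default_rng(seed)
    base_mats = materials
    traces = []
    abscissa = case.abscissa
    for s in range(n_specimens):
        cfg = _perturb_config(base_config, rng, spec)
        mats = None
        if base_mats is not None or spec.material_cv > 0.0:
            from .calibration import ligament_presets

            source = dict(base_mats or {n: p.material for n, p in ligament_presets().items()})
            mcl = _perturb_material(source["MCL"], rng, spec.material_cv)
            mats = {
                "ACL": _perturb_material(source["ACL"], rng, spec.material_cv),
                "PCL": _perturb_material(source["PCL"], rng, spec.material_cv),
                "MCL": mcl,
                "LCL": mcl,  # LCL follows MCL by construction
            }
        model = build_knee_model(
            cfg, "anatomic_3d", n_fibers_per_bundle=n_fibers_per_bundle, materials=mats
        )
        try:
            curve = run_load_case(model, case)
        except SolverError as err:
            raise SolverError(
                f"virtual specimen {s} failed on case {case.name!r}: {err}", residual=err.residual
            ) from err
        traces.append(curve.angle_values(case.primary_angle))

    Y = np.vstack(traces)
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    half = stats.t.ppf(0.975, n_specimens - 1) * sd
    return Corridor(
        abscissa=abscissa,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_specimens=n_specimens,
        angle=case.primary_angle,
        case_name=case.name,
    )


def default_geometry(symmetric: bool = False) -> dict:
    """Literature-plausible tibiofemoral geometry fixture.

    Replaces the unavailable CT/MRI geometry: mid-condylar world origin on
    the femoral flexion (z) axis, x anterior / y proximal / z medial (left
    knee), equal 21 mm condyle spheres touching the tibial plateau plane at
    full extension, attachment centroids and footprint sizes in the range
    of anatomical studies, Blankevoort-style truss constants, and ligament
    reference (pre-)strains at full extension.  All values are fixture
    choices, not source-study data.

    With `symmetric=True` all soft tissue is mirrored across the sagittal
    (z = 0) plane and muscle lines are centered, giving an exactly
    left-right symmetric model whose unloaded equilibrium has zero valgus
    and zero axial rotation — used for sanity checks.
    """
    cfg = {
        "condyles": {
            "medial": {"center": [0.0, 0.0, 22.0], "radius": 21.0},
            "lateral": {"center": [0.0, 0.0, -22.0], "radius": 21.0},
            "stiffness": 2000.0,
        },
        # tibial plateau with an 11 deg posterior slope (normal tilted in the
        # sagittal plane); internal rotation then carries the lateral
        # condyle onto lower surface, the medial-pivot mechanism coupling
        # internal rotation into valgus.  Plane point set so both condyles
        # touch exactly at full extension.
        "plateau": {"point": [0.0, -21.3931, 0.0], "normal": [-0.190809, 0.981627, 0.0]},
        "ligaments": {
            # anterior cruciate: posterior-lateral femoral notch wall to the
            # anteromedial tibial plateau; taut near extension (pre-strain)
            "ACL": {
                "femur": [-8.0, 2.0, -7.0],
                "tibia": [12.0, -21.0, 3.0],
                "footprint_major": 8.0,
                "footprint_minor": 4.5,
                "area": 40.0,
                "reference_strain": 0.04,
                "truss": {"k_total": 10000.0, "eps_l": 0.03, "n": 3},
            },
            # posterior cruciate: anteromedial notch to the posterior tibia,
            # slack at extension
            "PCL": {
                "femur": [5.0, 0.0, 7.0],
                "tibia": [-25.0, -27.0, -2.0],
                "footprint_major": 9.0,
                "footprint_minor": 5.0,
                "area": 45.0,
                "reference_strain": -0.02,
                "truss": {"k_total": 18000.0, "eps_l": 0.03, "n": 3},
            },
            # superficial MCL: medial epicondyle to the posteromedial crest
            # of the distal tibia (posterior offset makes internal rotation
            # slacken it -- the valgus/internal-rotation coupling mechanism)
            "MCL": {
                "femur": [0.0, 3.0, 45.0],
                "tibia": [-8.0, -85.0, 30.0],
                "footprint_major": 10.0,
                "footprint_minor": 4.0,
                "area": 25.0,
                "reference_strain": 0.03,
                "truss": {"k_total": 4000.0, "eps_l": 0.03, "n": 3},
            },
            # LCL: lateral epicondyle to the fibular head
            "LCL": {
                "femur": [0.0, 3.0, -42.0],
                "tibia": [-10.0, -55.0, -40.0],
                "footprint_major": 5.0,
                "footprint_minor": 3.0,
                "area": 10.0,
                "reference_strain": 0.02,
                "truss": {"k_total": 2000.0, "eps_l": 0.03, "n": 3},
            },
        },
        # capsule and corner structures (always trusses, both
        # representations): posterior capsule bundles, the oblique posterior
        # bundle (posterolateral tibia -> posteromedial femur, restrains
        # internal rotation near extension), the anterolateral structure
        # (ALS, the dominant internal-rotation restraint, with a large
        # horizontal lever) and the posterior oblique ligament (POL, a
        # weaker posteromedial internal-rotation restraint)
        "secondary": [
            {
                "name": "CAPm",
                "femur": [-15.0, 5.0, 20.0],
                "tibia": [-18.0, -25.0, 18.0],
                "k": 1500.0,
                "eps_l": 0.03,
                "reference_strain": 0.0,
            },
            {
                "name": "CAPl",
                "femur": [-15.0, 5.0, -20.0],
                "tibia": [-18.0, -25.0, -18.0],
                "k": 1500.0,
                "eps_l": 0.03,
                "reference_strain": 0.0,
            },
            {
                "name": "CAPo",
                "femur": [-15.0, 5.0, 15.0],
                "tibia": [-20.0, -25.0, -15.0],
                "k": 1500.0,
                "eps_l": 0.03,
                "reference_strain": 0.01,
            },
            {
                "name": "ALS",
                "femur": [0.0, 0.0, -40.0],
                "tibia": [18.0, -15.0, -22.0],
                "k": 600.0,
                "eps_l": 0.05,
                "reference_strain": -0.01,
            },
            {
                "name": "POL",
                "femur": [0.0, 2.0, 43.0],
                "tibia": [-14.0, -24.0, 20.0],
                "k": 300.0,
                "eps_l": 0.03,
                "reference_strain": 0.02,
            },
        ],
        # two resultant trans-knee muscle cables (quadriceps from the
        # tibial tuberosity toward a patellar via point, hamstrings from
        # the posterior tibia -- small medial offset -- toward a
        # proximal-posterior anchor)
        "muscles": {
            "quadriceps": {
                "attach_tibia": [25.0, -40.0, -3.0],
                "via_femur": [45.0, 15.0, -3.0],
                "force": 400.0,
            },
            "hamstrings": {
                "attach_tibia": [-20.0, -25.0, 4.0],
                "via_femur": [-60.0, 60.0, 4.0],
                "force": 200.0,
            },
        },
    }
    if symmetric:
        for lig in cfg["ligaments"].values():
            lig["femur"][2] = 0.0 if abs(lig["femur"][2]) < 15.0 else lig["femur"][2]
            lig["tibia"][2] = 0.0 if abs(lig["tibia"][2]) < 15.0 else lig["tibia"][2]
            # point attachments: the fiber sampling pattern is then exactly
            # mirror-symmetric, so the unloaded equilibrium is too
            lig["footprint_major"] = 0.0
            lig["footprint_minor"] = 0.0
        # mirror the collaterals exactly
        mcl, lcl = cfg["ligaments"]["MCL"], cfg["ligaments"]["LCL"]
        for key in ("femur", "tibia"):
            lcl[key] = [mcl[key][0], mcl[key][1], -mcl[key][2]]
        lcl["footprint_major"] = mcl["footprint_major"]
        lcl["footprint_minor"] = mcl["footprint_minor"]
        lcl["area"] = mcl["area"]
        lcl["reference_strain"] = mcl["reference_strain"]
        lcl["truss"] = copy.deepcopy(mcl["truss"])
        capm, capl = cfg["secondary"][0], cfg["secondary"][1]
        for key in ("femur", "tibia"):
            capl[key] = [capm[key][0], capm[key][1], -capm[key][2]]
        capl["k"], capl["eps_l"] = capm["k"], capm["eps_l"]
        cfg["secondary"] = cfg["secondary"][:2]  # drop the oblique bundle
        for m in cfg["muscles"].values():
            m["attach_tibia"][2] = 0.0
            m["via_femur"][2] = 0.0
    return cfg
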