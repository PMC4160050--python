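"""Least-squares identification of HGO coefficients from uniaxial tensile data.

A tensile curve (engineering strain vs. Cauchy stress) is fitted by the
closed-form incompressible uniaxial response of the HGO model.  Cruciate
(two-family) fits share c, k1, k2 and kappa across the two families and fit
a symmetric bundle half-angle +/-theta about the load axis — one uniaxial
curve cannot identify per-bundle coefficients.  The exponential fiber term
makes the problem multi-modal, so a seeded 5-restart multi-start wraps the
bounded trust-region least-squares solver; the best residual wins and the
result is never accepted if it is worse than the initial guess.

The preset registry mirrors the study's ligament assignments: two fiber
families for ACL and PCL, one for MCL and LCL, with LCL coefficients
identical to the MCL.  The numeric coefficients are plausible defaults in
the range of published ligament data (the source study does not print its
fitted values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constitutive import FiberFamily, HGOMaterial, uniaxial_stress
from .errors import UnderDeterminedError

__all__ = [
    "TensileCurve",
    "CalibrationResult",
    "LigamentPreset",
    "fit_material",
    "ligament_presets",
]

_PARAM_NAMES_1 = ("c", "k1", "k2", "kappa")
_PARAM_NAMES_2 = ("c", "k1", "k2", "kappa", "theta")
_BOUNDS = {
    "c": (1e-6, np.inf),
    "k1": (0.0, np.inf),
    "k2": (1e-6, np.inf),
    "kappa": (0.0, 1.0 / 3.0),
    "theta": (0.0, 45.0),
}
_MULTISTART_SEED = 20130501


@dataclass(frozen=True)
class TensileCurve:
    """Uniaxial tensile test record: engineering strain (-) vs. stress (MPa)."""

    strain: np.ndarray
    stress: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        s = np.asarray(self.strain, dtype=float)
        t = np.asarray(self.stress, dtype=float)
        if s.ndim != 1 or s.shape != t.shape:
            raise ValueError("strain and stress must be equal-length 1-D sequences")
        if s.size < 5:
            raise UnderDeterminedError(f"need at least 5 points, got {s.size}")
        if np.any(np.diff(s) <= 0.0):
            raise ValueError("strain must be strictly increasing")
        if s[0] < 0.0:
            raise ValueError("strain must start at >= 0")
        if np.any(t < 0.0):
            raise ValueError("stress must be non-negative")
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "stress", t)

    def __len__(self):
        return self.strain.size


@dataclass(frozen=True)
class CalibrationResult:
    material: HGOMaterial
    residual_rms: float
    converged: bool
    n_iterations: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class LigamentPreset:
    n_families: int
    material: HGOMaterial
    source: str


def _material_from_params(x: np.ndarray, n_families: int, recruitment: str) -> HGOMaterial:
    c, k1, k2, kappa = x[:4]
    kappa = min(max(kappa, 0.0), 1.0 / 3.0)
    if n_families == 1:
        fams = (FiberFamily((1.0, 0.0, 0.0), kappa, k1, k2),)
    else:
        th = np.radians(x[4])
        a = (float(np.cos(th)), float(np.sin(th)), 0.0)
        b = (float(np.cos(th)), float(-np.sin(th)), 0.0)
        fams = (
            FiberFamily(a, kappa, k1, k2),
            FiberFamily(b, kappa, k1, k2),
        )
    return HGOMaterial(c=max(c, 1e-12), families=fams, recruitment=recruitment)


def _params_from_material(mat: HGOMaterial, n_families: int) -> np.ndarray:
    fam = mat.families[0]
    x = [mat.c, fam.k1, fam.k2, fam.kappa]
    if n_families == 2:
        a = fam.direction
        x.append(float(np.degrees(np.arctan2(abs(a[1]), abs(a[0])))))
    return np.asarray(x, dtype=float)


def fit_material(
    curve: TensileCurve,
    n_families: int,
    init: HGOMaterial,
    fixed: set[str] | frozenset[str] | None = None,
    n_restarts: int = 5,
) -> CalibrationResult:
    """Fit HGO coefficients to a tensile curve by bounded least squares.

    Free coefficients are (c, k1, k2, kappa) plus the bundle half-angle
    theta for two-family fits, minus any names in `fixed` (held at their
    `init` values).  Deterministic given `init` (fixed internal multi-start
    seed).  Raises UnderDeterminedError if the curve has fewer points than
    free coefficients; non-convergence is reported via `converged=False`,
    never silently.
    """
    if n_families not in (1, 2):
        raise ValueError("n_families must be 1 or 2")
    names = _PARAM_NAMES_1 if n_families == 1 else _PARAM_NAMES_2
    fixed = frozenset(fixed or ())
    unknown = fixed - set(names)
    if unknown:
        raise ValueError(f"unknown fixed coefficient names: {sorted(unknown)}")
    free_idx = [i for i, n in enumerate(names) if n not in fixed]
    if len(curve) < len(free_idx):
        raise UnderDeterminedError(
            f"{len(curve)} points cannot determine {len(free_idx)} free coefficients"
        )

    x_full0 = _params_from_material(init, n_families)
    lam = 1.0 + curve.strain
    target = curve.stress
    recruitment = init.recruitment

    def full(x_free):
        x = x_full0.copy()
        x[free_idx] = x_free
        return x

    def residuals(x_free):
        mat = _material_from_params(full(x_free), n_families, recruitment)
        return uniaxial_stress(mat, lam) - target

    lo = np.array([_BOUNDS[names[i]][0] for i in free_idx])
    hi = np.array([_BOUNDS[names[i]][1] for i in free_idx])
    x0 = np.clip(x_full0[free_idx], lo, hi + 0.0)

    init_cost = float(np.sum(residuals(x0) ** 2))
    rng = np.random.default_rng(_MULTISTART_SEED)
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        pert = x0 * rng.lognormal(0.0, 0.3, size=x0.size) + rng.normal(0.0, 1e-3, x0.size)
        starts.append(np.clip(pert, lo, np.where(np.isinf(hi), np.abs(pert) + 1.0, hi)))

    best = None
    total_nfev = 0
    for s in starts:
        try:
            res = least_squares(
                residuals,
                s,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                x_scale="jac",
                max_nfev=2000,
            )
        except Exception:
            continue
        total_nfev += res.nfev
        cost = float(np.sum(res.fun**2))
        if best is None:
            best = (cost, res)
        else:
            # ties broken by lowest k2 (exponential models are multi-modal)
            bcost, bres = best
            if cost < bcost * (1.0 - 1e-12) - 1e-300:
                best = (cost, res)
            elif abs(cost - bcost) <= 1e-12 * (1.0 + bcost):
                k2_i = names.index("k2")
                if k2_i in free_idx:
                    j = free_idx.index(k2_i)
                    if res.x[j] < bres.x[j]:
                        best = (cost, res)

    if best is None or best[0] > init_cost:
        # monotone acceptance: never return something worse than the init
        mat = _material_from_params(x_full0, n_families, recruitment)
        rms = float(np.sqrt(init_cost / len(curve)))
        return CalibrationResult(mat, rms, converged=False, n_iterations=total_nfev)

    cost, res = best
    x_fit = full(res.x)
    mat = _material_from_params(x_fit, n_families, recruitment)
    rms = float(np.sqrt(cost / len(curve)))

    flags: list[str] = []
    if "k2" not in fixed:
        # flat-residual identifiability probe: doubling k2 must move the cost
        x_probe = x_fit.copy()
        x_probe[names.index("k2")] *= 2.0
        probe_cost = float(
            np.sum(
                (
                    uniaxial_stress(
                        _material_from_params(x_probe, n_families, recruitment), lam
                    )
                    - target
                )
                ** 2
            )
        )
        if abs(probe_cost - cost) <= 1e-10 * (1.0 + cost):
            flags.append("k2_unidentifiable")

    return CalibrationResult(
        mat,
        rms,
        converged=bool(res.success),
        n_iterations=int(total_nfev),
        flags=tuple(flags),
    )


def ligament_presets() -> dict[str, LigamentPreset]:
    """Default HGO materials per ligament.

    ACL and PCL carry two symmetric fiber families (anteromedial /
    posterolateral-style bundles); MCL (superficial) and LCL carry one, with
    the LCL coefficients identical to the MCL.  Coefficient values are
    plausible defaults in the range of published ligament tensile data
    (Butler-type cruciate and Quapp–Weiss-type MCL curves); the source study
    does not print its fitted coefficients.
    """
    mcl = HGOMaterial(
        c=1.44,
        families=(FiberFamily((1.0, 0.0, 0.0), kappa=0.02, k1=4.0, k2=60.0),),
    )
    acl = HGOMaterial(
        c=1.95,
        families=(
            FiberFamily((np.cos(np.radians(12.0)), np.sin(np.radians(12.0)), 0.0), 0.05, 3.5, 45.0),
            FiberFamily((np.cos(np.radians(12.0)), -np.sin(np.radians(12.0)), 0.0), 0.05, 3.5, 45.0),
        ),
    )
    pcl = HGOMaterial(
        c=3.25,
        families=(
            FiberFamily((np.cos(np.radians(15.0)), np.sin(np.radians(15.0)), 0.0), 0.05, 4.5, 50.0),
            FiberFamily((np.cos(np.radians(15.0)), -np.sin(np.radians(15.0)), 0.0), 0.05, 4.5, 50.0),
        ),
    )
    return {
        "ACL": LigamentPreset(2, acl, "Butler-type cruciate tensile data (plausible defaults)"),
        "PCL": LigamentPreset(2, pcl, "Butler-type cruciate tensile data (plausible defaults)"),
        "MCL": LigamentPreset(1, mcl, "Quapp-Weiss-type MCL tensile data (plausible defaults)"),
        "LCL": LigamentPreset(1, mcl, "assumed identical to MCL"),
    }
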