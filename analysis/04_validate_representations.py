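"""Score both ligament representations against the specimen corridors.

Reads the eight kinematic traces from 02 and the four corridors from 03,
computes Pearson r and RMSE against each corridor mean plus the fraction of
prediction points inside the 95% specimen band, and writes the comparison
table to results/report.csv.  The expected pattern — the one the study
design is built to expose — is the anatomic representation with higher r,
lower RMSE and full containment, and the uniaxial representation outside
the bands.

Run from the repository root (after 02 and 03):
    python analysis/04_validate_representations.py
"""

from pathlib import Path

from ligknee import build_report
from ligknee import io as lio

CURVES = Path("results/curves")
CORRIDORS = Path("results/corridors")


def main() -> None:
    corridors = {p.stem: lio.read_corridor(p) for p in CORRIDORS.glob("*.csv")}
    pred_3d, pred_1d = {}, {}
    for name, corr in corridors.items():
        pred_3d[name] = lio.read_kinematic_curve(
            CURVES / f"{name}_anatomic.csv", case_name=name, primary_angle=corr.angle
        )
        pred_1d[name] = lio.read_kinematic_curve(
            CURVES / f"{name}_uniaxial.csv", case_name=name, primary_angle=corr.angle
        )
    report = build_report(pred_3d, pred_1d, corridors)
    report.to_csv("results/report.csv", index=False)
    print(report.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))

    anat = report[report.representation == "anatomic_3d"]
    uni = report[report.representation == "uniaxial"]
    print(
        "\nAnatomic: r in [%.2f, %.2f], RMSE in [%.2f, %.2f] deg, containment >= %.2f"
        % (anat.r.min(), anat.r.max(), anat.rmse_deg.min(), anat.rmse_deg.max(), anat.containment.min())
    )
    print(
        "Uniaxial: r in [%.2f, %.2f], RMSE in [%.2f, %.2f] deg, containment <= %.2f"
        % (uni.r.min(), uni.r.max(), uni.rmse_deg.min(), uni.rmse_deg.max(), uni.containment.max())
    )
    print("Report written to results/report.csv")


if __name__ == "__main__":
    main()
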