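"""Internal consistency of the published thermodynamics of both complexes.

Checks dG = dH + (-TdS) and dG = -RT ln K at 298.15 K for the ITC data,
converts the MD free energies to theoretical constants at 300 K, and
derives the IDA applicability window from each probe's constant.
Findings go to results/thermo_consistency.csv.
"""

from pathlib import Path

import pandas as pd

from hgida.thermo import ThermoRecord, check_consistency, ida_window, k_from_gibbs

RESULTS = Path(__file__).resolve().parents[1] / "results"

# published values: dH, -TdS, dG (kcal/mol, ITC), K_itc (L/mol),
# dG from MD (kcal/mol), published K_theo (L/mol)
PUBLISHED = {
    "dq1_cb7": (-8.53, -0.71, -9.2, 5.9e6, -17.17, 3.27e12, 7.5e6),
    "dq2_cb7": (-9.36, -0.23, -9.6, 1.05e7, -18.23, 19.14e12, 1.1e7),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for label, (dh, mtds, dg, k_itc, dg_md, k_theo_pub, k_fluo) in PUBLISHED.items():
        rep = check_consistency(
            ThermoRecord(dH=dh, minus_TdS=mtds, dG=dg, k_bind=k_itc, label=label)
        )
        k_theo = k_from_gibbs(dg_md, 300.0)
        window = ida_window(k_fluo)
        rows.append(
            {
                "complex": label,
                "consistent": rep.consistent,
                "enthalpy_driven": rep.enthalpy_driven,
                "dG_from_k_kcal": round(rep.dG_from_k, 3),
                "dG_from_dH_minus_TdS_kcal": round(rep.dG_from_hs, 3),
                "k_theo_from_md": k_theo,
                "k_theo_published": k_theo_pub,
                "k_theo_rel_dev": round(k_theo / k_theo_pub - 1.0, 4),
                "ida_log_window_low": round(window.log_lower, 2),
                "ida_log_window_high": round(window.log_upper, 2),
            }
        )
        print(
            f"{label}: consistent={rep.consistent} enthalpy_driven={rep.enthalpy_driven} "
            f"-RT ln K = {rep.dG_from_k:.2f} kcal/mol; K_theo(300 K) = {k_theo:.3g} "
            f"({100 * (k_theo / k_theo_pub - 1):+.1f}% vs published); "
            f"IDA window 10^{window.log_lower:.2f}-10^{window.log_upper:.2f} L/mol"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "thermo_consistency.csv", index=False)
    print(f"wrote {RESULTS / 'thermo_consistency.csv'}")


if __name__ == "__main__":
    main()
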