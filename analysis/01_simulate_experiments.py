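"""Simulate every experiment design used downstream, with known truth.

Writes the seeded synthetic datasets (CSV + ground-truth sidecars) that
scripts 02-05 analyse, so the whole pipeline is reproducible offline.
"""

from pathlib import Path

import pandas as pd

from hgida import io, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 1
NOISE = 0.02  # relative Gaussian on fluorescence intensities


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for name in ("direct_dq1", "direct_dq2"):
        d = synthetic.replica_design(name)
        series = synthetic.gen_direct_titration(
            d["k_bind"], d["reporter_total"], d["host_grid"], d["i_free"], d["i_bound"],
            noise=synthetic.NoiseSpec("gaussian_relative", NOISE, SEED),
        )
        series.meta["fixed_totals"] = series.fixed_totals
        io.write_titration(series, OUT / f"{name}.csv")
        io.write_meta(series, OUT / f"{name}.meta.json")
        print(f"{name}: {len(series)} points, truth K = {d['k_bind']:.3g} L/mol")

    d = synthetic.replica_design("ida_mv")
    series = synthetic.gen_ida_titration(
        d["k1"], d["k2"], d["host_total"], d["indicator_total"], d["guest_grid"],
        d["i_complexed"], d["i_free_ind"],
        noise=synthetic.NoiseSpec("gaussian_relative", NOISE, SEED),
    )
    series.meta["fixed_totals"] = series.fixed_totals
    io.write_titration(series, OUT / "ida_mv.csv")
    io.write_meta(series, OUT / "ida_mv.meta.json")
    print(f"ida_mv: {len(series)} points, truth K2 = {d['k2']:.3g} L/mol")

    for name in ("ph_dq2", "ph_dq2_cb7"):
        d = synthetic.replica_design(name)
        series = synthetic.gen_ph_titration(
            d["pka"], d["a_acid"], d["a_base"], d["ph_grid"],
            noise=synthetic.NoiseSpec("gaussian_absolute", 0.005, SEED),
        )
        io.write_titration(series, OUT / f"{name}.csv")
        io.write_meta(series, OUT / f"{name}.meta.json")
        print(f"{name}: truth pKa = {d['pka']}")

    d = synthetic.replica_design("calibration_mv")
    conc, signal = synthetic.gen_calibration(
        d["slope"], d["intercept"], d["sigma"], d["conc_grid"], seed=SEED
    )
    pd.DataFrame({"conc": conc, "signal": signal}).to_csv(OUT / "calibration_mv.csv", index=False)
    io.write_meta({"truth": {k: d[k] for k in ("slope", "intercept", "sigma")}},
                  OUT / "calibration_mv.meta.json")
    print("calibration_mv: designed LOD 0.24 uM")

    d = synthetic.replica_design("decay_dq2_cb7")
    decay, irf = synthetic.gen_decay(
        d["taus"], d["fractions_percent"], d["irf_sigma_ns"],
        total_counts=d["total_counts"], seed=SEED,
    )
    pd.DataFrame({"time_ns": decay.time, "counts": decay.counts}).to_csv(
        OUT / "decay_dq2_cb7.csv", index=False
    )
    pd.DataFrame({"time_ns": irf.time, "counts": irf.counts}).to_csv(
        OUT / "decay_dq2_cb7_irf.csv", index=False
    )
    io.write_meta({"truth": {"taus_ns": list(d["taus"]),
                             "fractions_percent": list(d["fractions_percent"])}},
                  OUT / "decay_dq2_cb7.meta.json")
    print(f"decay_dq2_cb7: {d['total_counts']} counts, truth taus = {d['taus']} ns")


if __name__ == "__main__":
    main()
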