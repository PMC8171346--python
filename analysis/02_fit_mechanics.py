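"""Contractile analysis: Hill regression of force-pCa per genotype, the
pCa50 shift, and joint 3-state fits of force/kTR with perturbation
envelopes.

Reads results/inputs (run 01 first); writes results/mechanics.
"""

import json
from pathlib import Path

from tnckit import kinetics as kin
from tnckit.io import read_table, write_table

IN = Path("results/inputs")
OUT = Path("results/mechanics")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}

    hill = {}
    for label in ("WT", "C84Y"):
        df = read_table(IN / f"force_pca_{label}.csv")
        fit = kin.fit_hill(df, response="force", n_params=4)
        hill[label] = fit
        summary[f"pCa50_{label}"] = {"value": fit.pCa50, "se": fit.se["pCa50"]}
        summary[f"nHill_{label}"] = {"value": fit.nHill, "se": fit.se["nHill"]}
        print(f"{label}: pCa50 = {fit.pCa50:.3f} +/- {fit.se['pCa50']:.3f}, "
              f"nHill = {fit.nHill:.2f}")
    shift = hill["C84Y"].pCa50 - hill["WT"].pCa50
    summary["pCa50_shift"] = {"value": shift}
    print(f"Ca2+-sensitization (C84Y - WT): {shift:+.3f} pCa units")

    three = {}
    for label in ("WT", "C84Y"):
        df = read_table(IN / f"mechanics_3state_{label}.csv")
        fit = kin.fit_three_state(df, kON_fixed=100.0, seed=7)
        three[label] = fit
        summary[f"three_state_{label}"] = {
            "f": fit.f, "g": fit.g, "kOFF": fit.kOFF, "rss": fit.rss}
        print(f"{label}: f = {fit.f:.2f}, g = {fit.g:.2f}, kOFF = {fit.kOFF:.1f} 1/s")
    summary["f_ratio"] = {"value": three["C84Y"].f / three["WT"].f}
    summary["g_ratio"] = {"value": three["C84Y"].g / three["WT"].g}
    print(f"C84Y/WT rate ratios: f x{summary['f_ratio']['value']:.2f}, "
          f"g x{summary['g_ratio']['value']:.2f}")

    env = kin.perturbation_envelope(three["WT"])
    for frac, curve in env.items():
        write_table(curve, OUT / f"envelope_WT_{frac:+.2f}.csv")
    print(f"perturbation envelopes written for fractions {sorted(env)}")

    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
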