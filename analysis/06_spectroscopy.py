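"""Spectroscopic stability analysis: CD melt fitting with model selection
(two-domain unfolding vs single cooperative loss) and SAXS Kratky /
dimensionless-Kratky folding diagnostics.

Reads results/inputs (run 01 first); writes results/spectro.
"""

import json
from pathlib import Path

import numpy as np

from tnckit import spectro
from tnckit.io import read_table, write_table

IN = Path("results/inputs")
OUT = Path("results/spectro")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}

    for label in ("WT", "C84Y"):
        df = read_table(IN / f"melt_{label}.csv")
        best = spectro.select_melt_model(df["temperature_C"], df["signal"])
        summary[f"melt_{label}"] = {"n_transitions": best.n_transitions,
                                    "Tm": best.tm}
        tms = ", ".join(f"{t:.1f}" for t in best.tm)
        print(f"{label}: {best.n_transitions} transition(s), Tm = {tms} degC")

    for label in ("folded", "half", "unfolded"):
        prof = read_table(IN / f"saxs_{label}.csv")
        kt = spectro.kratky(prof)
        write_table(kt, OUT / f"kratky_{label}.csv")
        try:
            rg, i0 = spectro.guinier(prof)
            dk = spectro.dimensionless_kratky(prof, rg, i0)
            write_table(dk, OUT / f"kratky_dimensionless_{label}.csv")
            ipk = int(dk["kratky"].idxmax())
            peak = (float(dk["sRg"].iloc[ipk]), float(dk["kratky"].iloc[ipk]))
            interior = 0 < ipk < len(dk) - 1
            summary[f"saxs_{label}"] = {"Rg": rg, "peak_sRg": peak[0],
                                        "peak_height": peak[1],
                                        "bell_shaped": interior}
            shape = "bell-shaped" if interior else "plateau-like"
            print(f"{label}: Rg = {rg:.1f} A, dimensionless Kratky {shape}, "
                  f"max at sRg = {peak[0]:.2f} (height {peak[1]:.3f})")
        except ValueError as exc:
            summary[f"saxs_{label}"] = {"error": str(exc)}
            print(f"{label}: Guinier analysis not applicable ({exc})")

    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
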