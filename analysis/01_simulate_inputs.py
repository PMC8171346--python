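"""Generate every synthetic input class the downstream analyses consume.

Emulated study conditions: replicate force-pCa curves for both genotypes at
S.E.M.-scale noise, 3-state-consistent force/kTR tables, primed-state
(bimodal ~110/150 deg) and open-state (~102 deg) two-helix ensembles,
peptide titrations, relaxation decays, two-regime CPMG dispersions, one- and
two-transition CD melts, and folded/unfolded SAXS profiles.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

from pathlib import Path

from tnckit import kinetics as kin
from tnckit import synth
from tnckit.io import write_structure, write_table

SEED = 2021
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- cardiac muscle mechanics -------------------------------------
    for label, spec in synth.GENOTYPES.items():
        df = synth.gen_force_pca(spec, seed=SEED)
        write_table(df, OUT / f"force_pca_{label}.csv")
        print(f"force-pCa {label}: {len(df)} rows, true pCa50 {spec.pCa50}")

    act = kin.CaActivation()
    params = {
        "WT": kin.KineticParams(100.0, 50.0, 4.0, 2.0, act),
        # ~2x faster attachment, ~2x slower detachment, faster kOFF
        "C84Y": kin.KineticParams(100.0, 75.0, 8.0, 1.0, act),
    }
    for label, p in params.items():
        df = synth.gen_mechanics_3state(p, noise=0.03, replicates=6, seed=SEED)
        write_table(df, OUT / f"mechanics_3state_{label}.csv")
        print(f"3-state mechanics {label}: f={p.f} g={p.g} kOFF={p.kOFF}")

    # --- conformational ensembles -------------------------------------
    primed = synth.gen_two_helix_ensemble(
        synth.AngleDistSpec(components=((110.0, 5.0, 0.5), (150.0, 5.0, 0.5)),
                            n_models=400), seed=SEED)
    write_structure(primed, OUT / "ensemble_primed.pdb")
    open_state = synth.gen_two_helix_ensemble(
        synth.AngleDistSpec(components=((102.0, 5.0, 1.0),), n_models=400),
        seed=SEED + 1)
    write_structure(open_state, OUT / "ensemble_open.pdb")
    print("ensembles: primed (bimodal 110/150) and open (102 +/- 5), 400 models each")

    # --- NMR observables ----------------------------------------------
    titr = synth.gen_titration_peaklists(
        Kd=20.0, csp_max={r: 0.05 + 0.01 * (r % 7) for r in range(3, 90, 4)},
        Pt=100.0, seed=SEED)
    for conc, pl in titr.items():
        write_table(pl, OUT / f"titration_L{conc:g}.csv")
    rates = {r: 0.8 + 0.02 * r for r in range(3, 90)}
    write_table(synth.gen_relaxation_decays(rates, noise=0.02, seed=SEED),
                OUT / "r1_decays.csv")
    rates2 = {r: 8.0 + 0.2 * r for r in range(3, 90)}
    write_table(synth.gen_relaxation_decays(rates2, delays=synth.R2_DELAYS_S,
                                            noise=0.02, seed=SEED + 1),
                OUT / "r2_decays.csv")
    print(f"NMR: {len(titr)} titration points, R1/R2 decays for {len(rates)} residues")

    # --- spectroscopy -------------------------------------------------
    melts = {
        "WT": [(45.0, -6.0, 2.0), (62.0, -6.0, 2.5)],  # two-domain unfolding
        "C84Y": [(41.0, -11.0, 2.5)],                   # cooperativity loss
    }
    for label, trans in melts.items():
        write_table(synth.gen_melting_curve(trans, noise=0.1, seed=SEED),
                    OUT / f"melt_{label}.csv")
    for label, frac in (("folded", 1.0), ("unfolded", 0.0), ("half", 0.5)):
        write_table(synth.gen_saxs_profiles(Rg=15.0, folded_fraction=frac,
                                            noise=0.005, seed=SEED),
                    OUT / f"saxs_{label}.csv")
    print("spectroscopy: melts (WT two-transition, C84Y one) and SAXS mixtures")


if __name__ == "__main__":
    main()
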