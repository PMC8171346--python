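"""NMR observable calculators: CSP, temperature coefficients, relaxation
rates, CPMG dispersion and titration affinity fits.

Conventions (all config-exposed where the underlying experiment leaves them
open): chemical shifts in ppm, temperature coefficients in ppb/degC, rates
in 1/s, concentrations in uM.  The combined chemical-shift perturbation is

    CSP = sqrt( dH^2 + 0.1 * dN^2 )            [ppm]

with the usual 0.1 nitrogen weight.  The effective CPMG relaxation rate is
computed as R2eff = (1/T) ln(I0 / I_CPMG), which is positive for an
attenuated signal; ``as_printed=True`` flips the sign to match the literal
formula R2eff = -(1/T) ln(I0/I_CPMG) found in some methods sections.
Outlier flags use the population (1/n) standard deviation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "csp",
    "flag_above",
    "temp_coeff",
    "fit_rate",
    "r2_over_r1",
    "r2eff",
    "classify_exchange",
    "bound_fraction",
    "fit_kd",
    "TitrationFit",
]


def csp(reference: pd.DataFrame, query: pd.DataFrame) -> pd.DataFrame:
    """Chemical-shift perturbation per residue between two peak lists.

    Inputs need columns (residue, dH_ppm, dN_ppm).  Only the shared residue
    set is scored; residues present in exactly one list are reported in the
    ``only_reference`` / ``only_query`` attrs rather than imputed.
    """
    ref = reference.set_index("residue")
    qry = query.set_index("residue")
    shared = ref.index.intersection(qry.index)
    if len(shared) == 0:
        raise ValueError("peak lists share no residues")
    d_h = qry.loc[shared, "dH_ppm"] - ref.loc[shared, "dH_ppm"]
    d_n = qry.loc[shared, "dN_ppm"] - ref.loc[shared, "dN_ppm"]
    combined = np.sqrt(d_h**2 + 0.1 * d_n**2)
    out = pd.DataFrame({
        "residue": shared,
        "dH": d_h.to_numpy(),
        "dN": d_n.to_numpy(),
        "CSP": combined.to_numpy(),
    })
    mean, sd = out["CSP"].mean(), out["CSP"].std(ddof=0)
    out["above_1sd"] = out["CSP"] > mean + sd
    out["above_2sd"] = out["CSP"] > mean + 2 * sd
    out.attrs["only_reference"] = sorted(ref.index.difference(qry.index))
    out.attrs["only_query"] = sorted(qry.index.difference(ref.index))
    return out


def flag_above(values: pd.Series | np.ndarray, k: float = 1.0, residues=None) -> list:
    """Residues whose statistic exceeds mean + k * SD (population SD)."""
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need at least 3 residues to flag outliers")
    idx = np.asarray(residues) if residues is not None else np.arange(v.size)
    cut = v.mean() + k * v.std(ddof=0)
    return [x for x, val in zip(idx, v) if val > cut]


def temp_coeff(series: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Amide-proton temperature coefficients, ppb/degC, by OLS per residue.

    ``series`` maps temperature (degC) to a peak list (residue, dH_ppm).
    Residues observed at fewer than 3 temperatures are skipped (flagged in
    ``attrs['skipped']``); a constant shift reports slope 0 with R2 = 0 and
    ``degenerate=True``.
    """
    temps = sorted(series)
    if len(temps) < 3:
        raise ValueError("need at least 3 temperatures")
    tables = {t: series[t].set_index("residue") for t in temps}
    residues = sorted(set().union(*[set(tb.index) for tb in tables.values()]))
    rows, skipped = [], []
    for res in residues:
        t_obs, d_obs = [], []
        for t in temps:
            if res in tables[t].index:
                t_obs.append(t)
                d_obs.append(tables[t].loc[res, "dH_ppm"] * 1000.0)  # ppm -> ppb
        if len(t_obs) < 3:
            skipped.append(res)
            continue
        t_arr, d_arr = np.array(t_obs, float), np.array(d_obs, float)
        if np.ptp(d_arr) == 0.0:
            rows.append({"residue": res, "slope_ppb_per_C": 0.0,
                         "intercept_ppb": d_arr[0], "r2": 0.0, "degenerate": True})
            continue
        lr = stats.linregress(t_arr, d_arr)
        rows.append({"residue": res, "slope_ppb_per_C": lr.slope,
                     "intercept_ppb": lr.intercept, "r2": lr.rvalue**2,
                     "degenerate": False})
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def fit_rate(delays, intensities) -> tuple[float, float]:
    """Mono-exponential relaxation fit I(t) = I0 exp(-R t); returns (R, SE).

    Initial guess from log-linear regression; nonlinear refinement by
    curve_fit.  Non-decaying data converge to R ~ 0 rather than erroring so
    flat reference residues survive batch processing; a genuinely rising
    signal raises.
    """
    t = np.asarray(delays, float)
    y = np.asarray(intensities, float)
    if len(t) < 4:
        raise ValueError("need at least 4 delays")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    r0 = max(-slope, 0.0)

    def model(t_, i0, r):
        return i0 * np.exp(-r * t_)

    popt, pcov = optimize.curve_fit(
        model, t, y, p0=[np.exp(intercept), r0],
        bounds=([0, -np.inf], [np.inf, np.inf]), maxfev=10000,
    )
    r = float(popt[1])
    # a clearly rising signal (>5% net growth over the delay range) is not a
    # relaxation decay; tiny negative rates from noise pass through as ~0
    if r < 0 and -r * (t.max() - t.min()) > 0.05:
        raise RuntimeError("signal rises with delay; not a relaxation decay")
    se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return r, se


def fit_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Batch :func:`fit_rate` over a long table (residue, delay_s, intensity)."""
    rows = []
    for res, grp in table.groupby("residue"):
        try:
            r, se = fit_rate(grp["delay_s"], grp["intensity"])
            rows.append({"residue": res, "rate": r, "se": se, "ok": True})
        except (RuntimeError, ValueError):
            rows.append({"residue": res, "rate": np.nan, "se": np.nan, "ok": False})
    return pd.DataFrame(rows)


def r2_over_r1(
    r1: pd.DataFrame,
    r2: pd.DataFrame,
    domain_split: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-residue R2/R1 with per-domain mean/SD and mean+1SD flags.

    Default domain split follows the two-lobed architecture of cTnC around
    the D/E linker: N-domain 1-85, C-domain 94-161.  Residues with R1 = 0
    are masked, not dropped.
    """
    domain_split = domain_split or {"N": (1, 85), "C": (94, 161)}
    merged = r1.merge(r2, on="residue", suffixes=("_r1", "_r2"))
    rate1 = merged["rate_r1"].to_numpy(float)
    rate2 = merged["rate_r2"].to_numpy(float)
    ratio = np.where(rate1 != 0, rate2 / np.where(rate1 == 0, np.nan, rate1), np.nan)
    out = pd.DataFrame({"residue": merged["residue"], "ratio": ratio})

    def domain_of(res):
        for name, (lo, hi) in domain_split.items():
            if lo <= res <= hi:
                return name
        return "linker"

    out["domain"] = out["residue"].map(domain_of)
    out["flag"] = False
    stats_rows = {}
    for name in domain_split:
        sel = (out["domain"] == name) & out["ratio"].notna()
        vals = out.loc[sel, "ratio"]
        if len(vals) == 0:
            continue
        mean, sd = vals.mean(), vals.std(ddof=0)
        stats_rows[name] = {"mean": mean, "sd": sd}
        out.loc[sel & (out["ratio"] > mean + sd), "flag"] = True
    out.attrs["domain_stats"] = stats_rows
    return out


def r2eff(I0: float, Icpmg: float, T: float, as_printed: bool = False) -> float:
    """Effective transverse relaxation rate from CPMG intensities.

    (1/T) ln(I0 / I_CPMG), positive for attenuated signal.  ``as_printed``
    reproduces the sign of the literal formula -1/T ln(I0/I_CPMG).
    """
    if I0 <= 0 or Icpmg <= 0:
        raise ValueError("intensities must be positive")
    if T <= 0:
        raise ValueError("relaxation period must be positive")
    val = np.log(I0 / Icpmg) / T
    return float(-val if as_printed else val)


def classify_exchange(
    table: pd.DataFrame,
    eps: float | None = None,
    delta: float | None = None,
) -> pd.DataFrame:
    """Per-residue exchange-regime call from two-frequency CPMG data.

    ``table`` columns: residue, R2eff_50, R2eff_1000 (1/s).  Rules, applied
    against the cohort of all residues:

    * fast — dispersion flat (|R2eff_50 - R2eff_1000| <= eps) but the mean
      R2eff sits more than 1 SD above the cohort average;
    * intermediate — R2eff decays with refocusing frequency
      (R2eff_50 - R2eff_1000 > delta) and R2eff_50 is more than 1 SD above
      the cohort average;
    * none — everything else.

    Defaults: eps = delta = max(2 1/s, 10% of the cohort mean).  The call
    depends only on rates, so it is invariant to intensity rescaling.
    """
    if len(table) < 5:
        raise ValueError("cohort must contain at least 5 residues")
    r50 = table["R2eff_50"].to_numpy(float)
    r1000 = table["R2eff_1000"].to_numpy(float)
    cohort = np.concatenate([r50, r1000])
    mean, sd = cohort.mean(), cohort.std(ddof=0)
    if eps is None:
        eps = max(2.0, 0.1 * mean)
    if delta is None:
        delta = eps
    disp = r50 - r1000
    avg = 0.5 * (r50 + r1000)
    regime = np.full(len(table), "none", dtype=object)
    fast = (np.abs(disp) <= eps) & (avg > mean + sd)
    inter = (disp > delta) & (r50 > mean + sd)
    regime[fast] = "fast"
    regime[inter] = "intermediate"  # decaying dispersion wins over flat
    out = table.copy()
    out["dispersion"] = disp
    out["regime"] = regime
    out.attrs["cohort_mean"] = float(mean)
    out.attrs["cohort_sd"] = float(sd)
    return out


def bound_fraction(L, Pt: float, Kd: float):
    """1:1 binding isotherm — fraction of protein bound at total ligand L.

    Quadratic (ligand-depletion) solution, exact for a single site."""
    L = np.asarray(L, float)
    s = Pt + L + Kd
    return (s - np.sqrt(s**2 - 4.0 * Pt * L)) / (2.0 * Pt)


@dataclass
class TitrationFit:
    Kd: float
    Kd_se: float
    csp_max: dict
    csp_max_se: dict
    Pt: float
    warning: str | None = None


def fit_kd(data: pd.DataFrame, Pt: float) -> TitrationFit:
    """Global titration fit: shared Kd, per-residue CSPmax.

    ``data`` columns: ligand_uM, CSP_ppm and optionally residue (absent or
    constant -> pooled single-series fit).  CSP(L) = CSPmax * bound_fraction.
    Requires >= 4 ligand points including 0.  If saturation is not
    approached (max CSP < 2x the first nonzero point) the Kd is flagged as
    ill-conditioned in ``warning``.
    """
    df = data.copy()
    if "residue" not in df.columns:
        df["residue"] = "pooled"
    ligands = np.sort(df["ligand_uM"].unique())
    if len(ligands) < 4 or ligands[0] != 0:
        raise ValueError("need >= 4 ligand points including 0")
    residues = list(df["residue"].unique())

    L = df["ligand_uM"].to_numpy(float)
    y = df["CSP_ppm"].to_numpy(float)
    res_idx = df["residue"].map({r: i for i, r in enumerate(residues)}).to_numpy()

    def resid(theta):
        kd = np.exp(theta[0])
        amps = theta[1:]
        return amps[res_idx] * bound_fraction(L, Pt, kd) - y

    amp0 = [max(df.loc[df["residue"] == r, "CSP_ppm"].max(), 1e-6) for r in residues]
    theta0 = np.concatenate([[np.log(Pt)], amp0])
    sol = optimize.least_squares(resid, theta0, max_nfev=20000)
    kd = float(np.exp(sol.x[0]))
    amps = sol.x[1:]
    dof = max(len(y) - len(sol.x), 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        kd_se = kd * se[0]
        amp_se = se[1:]
    except np.linalg.LinAlgError:
        kd_se = np.nan
        amp_se = np.full(len(amps), np.nan)

    warning = None
    per_res_warn = []
    for r in residues:
        sub = df[df["residue"] == r].sort_values("ligand_uM")
        nonzero = sub[sub["ligand_uM"] > 0]
        if len(nonzero) and nonzero["CSP_ppm"].max() < 2 * nonzero["CSP_ppm"].iloc[0]:
            per_res_warn.append(r)
    if per_res_warn:
        warning = f"saturation not approached for {per_res_warn}; Kd ill-conditioned"

    return TitrationFit(
        Kd=kd,
        Kd_se=float(kd_se),
        csp_max=dict(zip(residues, amps)),
        csp_max_se=dict(zip(residues, amp_se)),
        Pt=Pt,
        warning=warning,
    )
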