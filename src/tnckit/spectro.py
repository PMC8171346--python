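"""Circular-dichroism melt analysis and SAXS Kratky/Guinier transforms.

CD thermograms (ellipticity at 222 nm vs temperature) are converted to mean
residue ellipticity and fitted with linear pre/post baselines plus one or
two two-state sigmoids; a loss of the second transition is the signature of
lost unfolding cooperativity between the two globular domains.  SAXS
profiles are transformed to Kratky (s^2 I vs s) and dimensionless Kratky
((sRg)^2 I/I0 vs sRg) representations; a compact globule shows a bell with
its dimensionless peak at (sqrt(3), 3/e), an unfolded chain a monotone rise
to a plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "mre",
    "MeltFit",
    "fit_melt",
    "kratky",
    "guinier",
    "dimensionless_kratky",
]


def mre(theta_mdeg, MW: float, n_bonds: int, path_cm: float, conc_mg_ml: float):
    """Mean residue ellipticity, deg cm^2 dmol^-1 res^-1.

    [theta]_MRE = theta * 0.1 * (MW / n) / (l * c): ellipticity in
    millidegrees, molecular weight in Da, n peptide bonds, path length in
    cm, concentration in mg/ml.  The denominator groups as l*c — the only
    dimensionally consistent reading.
    """
    if MW <= 0 or n_bonds <= 0:
        raise ValueError("MW and n_bonds must be positive")
    if path_cm <= 0 or conc_mg_ml <= 0:
        raise ValueError("path length and concentration must be positive")
    return np.asarray(theta_mdeg, float) * 0.1 * (MW / n_bonds) / (path_cm * conc_mg_ml)


def _melt_model(T, baseline0, baseline_slope, amps, tms, widths):
    y = baseline0 + baseline_slope * T
    for a, tm, k in zip(amps, tms, widths):
        z = np.clip((tm - T) / max(k, 1e-9), -500.0, 500.0)
        y = y + a / (1.0 + np.exp(z))
    return y


@dataclass
class MeltFit:
    tm: list[float]
    tm_se: list[float]
    amplitude: list[float]
    width: list[float]
    baseline: tuple[float, float]
    n_transitions: int
    rss: float
    aic: float

    def predict(self, T):
        return _melt_model(np.asarray(T, float), self.baseline[0], self.baseline[1],
                           self.amplitude, self.tm, self.width)


def fit_melt(temperature, signal, n_transitions: int = 1) -> MeltFit:
    """Thermal-unfolding fit: linear baseline + 1 or 2 Boltzmann sigmoids.

    Multi-start over a Tm grid spanning the data; for two transitions the
    Tm values are reported in increasing order.  Model comparison between
    the 1- and 2-transition fits goes through the ``aic`` field
    (Gaussian-residual AIC).

    Tm is bounded to the data range and transition widths to [0.5, 25] degC:
    protein unfolding transitions are always degrees wide, and a sigmoid
    narrower than the temperature grid is unidentifiable — it can only chase
    single noise excursions.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    T = np.asarray(temperature, float)
    y = np.asarray(signal, float)
    if len(T) < 15:
        raise ValueError("need >= 15 temperature points spanning the baselines")

    amp_scale = y.max() - y.min()
    if amp_scale == 0:
        amp_scale = 1.0
    span = T.max() - T.min()

    def pack_model(T_, *theta):
        b0, b1 = theta[0], theta[1]
        rest = theta[2:]
        amps = rest[0::3]
        tms = rest[1::3]
        widths = np.abs(rest[2::3])
        return _melt_model(T_, b0, b1, amps, tms, widths)

    lo = [-np.inf, -np.inf] + [-np.inf, T.min(), 0.5] * n_transitions
    hi = [np.inf, np.inf] + [np.inf, T.max(), 25.0] * n_transitions

    grid = np.linspace(T.min() + 0.15 * span, T.max() - 0.15 * span, 5)
    starts = []
    if n_transitions == 1:
        for tm0 in grid:
            starts.append([y[0], 0.0, amp_scale, tm0, 2.0])
    else:
        for i, tm0 in enumerate(grid):
            for tm1 in grid[i + 1:]:
                starts.append([y[0], 0.0, amp_scale / 2, tm0, 2.0,
                               amp_scale / 2, tm1, 2.0])

    best = None
    diagnostics = []
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(pack_model, T, y, p0=p0,
                                            bounds=(lo, hi), maxfev=30000)
        except RuntimeError as exc:
            diagnostics.append(str(exc))
            continue
        rss = float(np.sum((pack_model(T, *popt) - y) ** 2))
        if best is None or rss < best[2] - 1e-12:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError(
            f"melt fit failed from all {len(starts)} starts: {diagnostics[:2]}"
        )
    popt, pcov, rss = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    amps = list(popt[2::3])
    tms = list(popt[3::3])
    widths = [abs(w) for w in popt[4::3]]
    tm_se = list(perr[3::3])
    order = np.argsort(tms)
    n = len(y)
    k = len(popt)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    fit = MeltFit(
        tm=[float(tms[i]) for i in order],
        tm_se=[float(tm_se[i]) for i in order],
        amplitude=[float(amps[i]) for i in order],
        width=[float(widths[i]) for i in order],
        baseline=(float(popt[0]), float(popt[1])),
        n_transitions=n_transitions,
        rss=rss,
        aic=float(aic),
    )
    for tm in fit.tm:
        if not (T.min() - 5 <= tm <= T.max() + 5):
            raise RuntimeError(f"fitted Tm {tm:.1f} degC outside the data range")
    return fit


def select_melt_model(temperature, signal, min_amp_fraction: float = 0.05) -> MeltFit:
    """Fit both 1- and 2-transition models and keep the lower AIC.

    A movable second sigmoid is unidentified under a single-transition
    truth, so raw AIC over-selects it by chasing noise excursions.  The
    2-transition model is therefore only admissible if both transitions are
    physically resolved:

    * each amplitude carries at least ``min_amp_fraction`` of the total
      transition amplitude (a bump at the noise floor is not a transition);
    * the amplitudes share a sign — at 222 nm every unfolding step moves
      ellipticity the same way, toward the unfolded baseline;
    * the Tm values are separated by more than the mean transition width
      (closer than that, two sigmoids are one transition re-parameterized).
    """
    one = fit_melt(temperature, signal, 1)
    try:
        two = fit_melt(temperature, signal, 2)
    except RuntimeError:
        return one
    total = sum(abs(a) for a in two.amplitude)
    resolved = (
        total > 0
        and min(abs(a) for a in two.amplitude) >= min_amp_fraction * total
        and two.amplitude[0] * two.amplitude[1] > 0
        and abs(two.tm[1] - two.tm[0]) > 0.5 * (two.width[0] + two.width[1])
    )
    if not resolved:
        return one
    return two if two.aic < one.aic else one


def kratky(profile: pd.DataFrame) -> pd.DataFrame:
    """Kratky transform: (s, s^2 I(s)); elementwise, no smoothing."""
    s = profile["s"].to_numpy(float)
    if np.any(s <= 0) or np.any(np.diff(s) <= 0):
        raise ValueError("s grid must be positive and strictly increasing")
    return pd.DataFrame({"s": s, "s2I": s**2 * profile["I"].to_numpy(float)})


def guinier(profile: pd.DataFrame, srg_limit: float = 1.3) -> tuple[float, float]:
    """Radius of gyration and I0 from the Guinier region.

    Linear regression of ln I vs s^2; the window s*Rg <= srg_limit is
    enforced iteratively (fit, shrink window to the new Rg, repeat until
    stable).  Returns (Rg in A, I0).
    """
    s = profile["s"].to_numpy(float)
    I = profile["I"].to_numpy(float)
    keep = I > 0
    s, I = s[keep], I[keep]
    window = np.ones(len(s), dtype=bool)
    rg = None
    for _ in range(50):
        if window.sum() < 5:
            raise ValueError("Guinier window contains fewer than 5 points")
        slope, intercept = np.polyfit(s[window] ** 2, np.log(I[window]), 1)
        if slope >= 0:
            raise ValueError("non-decaying profile: no Guinier region")
        rg_new = float(np.sqrt(-3.0 * slope))
        new_window = s * rg_new <= srg_limit
        if rg is not None and abs(rg_new - rg) < 1e-9:
            break
        rg = rg_new
        if new_window.sum() == window.sum() and np.all(new_window == window):
            break
        window = new_window
    return rg, float(np.exp(intercept))


def dimensionless_kratky(profile: pd.DataFrame, Rg: float, I0: float) -> pd.DataFrame:
    """Dimensionless Kratky transform ((sRg), (sRg)^2 I/I0).

    For an ideal compact globule the curve peaks at sRg = sqrt(3) with
    height 3/e ~ 1.104; scaling I by any constant leaves it unchanged.
    """
    if Rg <= 0 or I0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    s = profile["s"].to_numpy(float)
    x = s * Rg
    return pd.DataFrame({"sRg": x, "kratky": x**2 * profile["I"].to_numpy(float) / I0})
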