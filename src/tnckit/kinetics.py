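"""Three-state sarcomere contraction model and contractile-data regression.

The model is a linear kinetic scheme over regulatory/cross-bridge states

    B (blocked)  <-- kOFF / kON*alpha(pCa) -->  C (permissive, detached)
    C  <-- g / f -->  M (attached, force generating)

where alpha(pCa) is the Hill occupancy of the regulatory Ca2+ site
(site II of cTnC) and isometric force is proportional to the M occupancy,
normalized to its value at saturating Ca2+ (pCa 4.0).  The scheme carries
the four named rates of the tension-redevelopment literature: kON/kOFF for
regulatory-unit dynamics, f/g for cross-bridge attachment/detachment, all
in 1/s.  Two classical limits anchor the behaviour: at saturating Ca2+ with
fast regulatory dynamics, the tension-redevelopment rate kTR -> f + g, and
slowing kOFF elevates the low-force end of the force-kTR relation.

Fitting entry points:

* :func:`fit_hill` — 2/3/4-parameter Hill regression of force(pCa) (or
  sinusoidal stiffness), as used for pCa50 / nHill estimation.
* :func:`fit_three_state` — joint weighted fit of force-pCa and force-kTR
  for (f, g, kOFF) with kON held fixed, multi-start, log-parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "CaActivation",
    "KineticParams",
    "HillFit",
    "ThreeStateFit",
    "hill_curve",
    "rate_matrix",
    "steady_state",
    "ktr",
    "fit_hill",
    "fit_three_state",
    "perturbation_envelope",
]

SATURATING_PCA = 4.0


@dataclass(frozen=True)
class CaActivation:
    """Hill occupancy of the regulatory Ca2+ site: alpha(pCa)."""

    pCa50_act: float = 5.85
    n_act: float = 2.0

    def __post_init__(self):
        if self.n_act <= 0:
            raise ValueError("n_act must be positive")

    def alpha(self, pCa) -> np.ndarray | float:
        # alpha = [Ca]^n / ([Ca]^n + Ca50^n) rewritten in pCa units
        return 1.0 / (1.0 + 10.0 ** (self.n_act * (np.asarray(pCa, float) - self.pCa50_act)))


@dataclass(frozen=True)
class KineticParams:
    """Rates of the B<->C<->M scheme, all in 1/s."""

    kON: float
    kOFF: float
    f: float
    g: float
    activation: CaActivation = field(default_factory=CaActivation)

    def __post_init__(self):
        # zero rates are tolerated so degenerate limits (f=0, kOFF=0) can be
        # exercised; negative rates never are
        for name in ("kON", "kOFF", "f", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.kON <= 0:
            raise ValueError("kON must be positive")

    def scaled(self, factor: float) -> "KineticParams":
        """All four rates scaled jointly (activation untouched)."""
        return KineticParams(
            self.kON * factor, self.kOFF * factor, self.f * factor,
            self.g * factor, self.activation,
        )


#: Reference parameter set used by the synthetic generators; rates chosen so
#: that kTR saturates near f+g ~ 6 1/s (mouse CMP scale) with regulatory
#: dynamics an order of magnitude faster.
REFERENCE_PARAMS = KineticParams(kON=100.0, kOFF=50.0, f=4.0, g=2.0)


def rate_matrix(params: KineticParams, pCa: float) -> np.ndarray:
    """Generator matrix Q over (B, C, M), column convention dP/dt = Q @ P.

    Columns sum to zero (probability conservation)."""
    a = float(params.activation.alpha(pCa))
    kon = params.kON * a
    Q = np.array(
        [
            [-kon, params.kOFF, 0.0],
            [kon, -(params.kOFF + params.f), params.g],
            [0.0, params.f, -params.g],
        ]
    )
    return Q


def steady_state(params: KineticParams, pCa: float) -> dict:
    """Steady-state occupancies and force (M normalized at pCa 4.0).

    The stationary distribution of the linear chain has the detailed-balance
    closed form B:C:M = kOFF/(kON*alpha) : 1 : f/g.
    """
    a = float(params.activation.alpha(pCa))
    if params.g == 0.0:
        if params.f > 0 and a > 0:
            return {"B": 0.0, "C": 0.0, "M": 1.0, "force": 1.0}  # M absorbing
        raise ValueError("degenerate rates: no unique steady state")
    f_over_g = params.f / params.g
    if a > 0:
        b_over_c = params.kOFF / (params.kON * a)
        c = 1.0 / (1.0 + b_over_c + f_over_g)
        occ = np.array([b_over_c * c, c, f_over_g * c])
    else:  # B absorbing
        occ = np.array([1.0, 0.0, 0.0])
    m_sat = _m_at(params, SATURATING_PCA)
    force = occ[2] / m_sat if m_sat > 0 else 0.0
    return {"B": occ[0], "C": occ[1], "M": occ[2], "force": force}


def _m_at(params: KineticParams, pCa: float) -> float:
    a = float(params.activation.alpha(pCa))
    if a == 0:
        return 0.0
    f_over_g = params.f / params.g
    b_over_c = params.kOFF / (params.kON * a)
    return f_over_g / (1.0 + b_over_c + f_over_g)


def steady_state_ode(params: KineticParams, pCa: float, horizon: float | None = None) -> np.ndarray:
    """Long-time ODE occupancies — the brute-force oracle for steady_state.

    Propagates P(t) = expm(Q t) P0 from the uniform distribution for a time
    long relative to the slowest rate."""
    Q = rate_matrix(params, pCa)
    rates = [params.kON, params.kOFF, params.f, params.g]
    t = horizon if horizon is not None else 1000.0 / min(rates)
    P0 = np.full(3, 1.0 / 3.0)
    return linalg.expm(Q * t) @ P0


def ktr(params: KineticParams, pCa: float, method: str = "eigen") -> float:
    """Rate of isometric tension redevelopment at a given activation.

    ``eigen``: smallest-magnitude nonzero eigenvalue of the rate matrix —
    the relaxation rate that dominates the mono-exponential force rise.
    ``simulate``: re-enact the release-restretch maneuver (all cross-bridges
    detached, regulatory state preserved), integrate M(t), and fit a
    mono-exponential over the 5-95% force-rise window.
    """
    Q = rate_matrix(params, pCa)
    if method == "eigen":
        ev = np.linalg.eigvals(Q)
        nonzero = sorted(abs(ev[np.abs(ev) > 1e-10 * max(1.0, np.abs(ev).max())]))
        if not nonzero:
            raise ValueError("rate matrix has no nonzero eigenvalue")
        return float(nonzero[0])
    if method != "simulate":
        raise ValueError(f"unknown ktr method: {method}")

    ss = steady_state(params, pCa)
    m_inf = ss["M"]
    if m_inf <= 0:
        raise ValueError("no force develops at this activation; kTR undefined")
    # post-slack initial condition: M = 0, B and C keep their steady ratio
    bc = ss["B"] + ss["C"]
    P0 = np.array([ss["B"], ss["C"], 0.0])
    P0[:2] = P0[:2] / bc * 1.0 if bc > 0 else np.array([0.5, 0.5])
    # span the transient out to several times the slowest relaxation mode
    ev = np.abs(np.linalg.eigvals(Q))
    slow = ev[ev > 1e-10 * max(1.0, ev.max())].min()
    t = np.linspace(0.0, 8.0 / slow, 400)
    m_t = np.array([(linalg.expm(Q * ti) @ P0)[2] for ti in t])
    rise = m_t / m_inf
    window = (rise >= 0.05) & (rise <= 0.95)
    if window.sum() < 5:
        raise RuntimeError("tension-rise window too short for exponential fit")
    tw, mw = t[window], m_t[window]

    # single-exponential approach with free rate and amplitude scale
    def model(t_, k, amp):
        return amp * (1.0 - np.exp(-k * t_))

    popt, _ = optimize.curve_fit(
        model, tw, mw, p0=[1.0 / (tw[-1] - tw[0] + 1e-12), m_inf], maxfev=10000
    )
    if not np.isfinite(popt[0]) or popt[0] <= 0:
        raise RuntimeError("exponential fit for kTR did not converge")
    return float(popt[0])


def hill_curve(pCa, pCa50: float, nH: float, Fmin: float = 0.0, Fmax: float = 1.0):
    """Hill equation on the pCa axis (force rises as pCa falls)."""
    return Fmin + (Fmax - Fmin) / (1.0 + 10.0 ** (nH * (np.asarray(pCa, float) - pCa50)))


@dataclass
class HillFit:
    pCa50: float
    nHill: float
    Fmin: float
    Fmax: float
    se: dict[str, float]
    n_params: int
    rss: float

    def predict(self, pCa):
        return hill_curve(pCa, self.pCa50, self.nHill, self.Fmin, self.Fmax)


def fit_hill(data: pd.DataFrame, response: str = "force", n_params: int = 4) -> HillFit:
    """Least-squares Hill regression of ``response`` against pCa.

    n_params: 2 fixes Fmin=0, Fmax=1; 3 frees Fmax; 4 frees both.
    Standard errors come from the Jacobian at the optimum.
    """
    if n_params not in (2, 3, 4):
        raise ValueError("n_params must be 2, 3 or 4")
    df = data.dropna(subset=["pCa", response])
    x = df["pCa"].to_numpy(float)
    y = df[response].to_numpy(float)
    if len(np.unique(x)) < n_params + 1:
        raise ValueError("need more distinct pCa values than parameters")

    guesses = {
        "pCa50": 0.5 * (x.min() + x.max()),
        "nHill": 2.0,
        "Fmax": float(np.nanmax(y)),
        "Fmin": float(np.nanmin(y)),
    }

    if n_params == 2:
        def model(x_, p50, nh):
            return hill_curve(x_, p50, nh, 0.0, 1.0)
        p0 = [guesses["pCa50"], guesses["nHill"]]
        names = ["pCa50", "nHill"]
    elif n_params == 3:
        def model(x_, p50, nh, fmax):
            return hill_curve(x_, p50, nh, 0.0, fmax)
        p0 = [guesses["pCa50"], guesses["nHill"], guesses["Fmax"]]
        names = ["pCa50", "nHill", "Fmax"]
    else:
        def model(x_, p50, nh, fmax, fmin):
            return hill_curve(x_, p50, nh, fmin, fmax)
        p0 = [guesses["pCa50"], guesses["nHill"], guesses["Fmax"], guesses["Fmin"]]
        names = ["pCa50", "nHill", "Fmax", "Fmin"]

    best = None
    for p50_start in np.linspace(x.min(), x.max(), 5):
        p0_try = list(p0)
        p0_try[0] = p50_start
        try:
            popt, pcov = optimize.curve_fit(model, x, y, p0=p0_try, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2] - 1e-15:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from every start")
    popt, pcov, rss = best
    se = dict(zip(names, np.sqrt(np.clip(np.diag(pcov), 0, None))))
    vals = dict(zip(names, popt))
    fit = HillFit(
        pCa50=float(vals["pCa50"]),
        nHill=float(vals["nHill"]),
        Fmin=float(vals.get("Fmin", 0.0)),
        Fmax=float(vals.get("Fmax", 1.0)),
        se=se,
        n_params=n_params,
        rss=rss,
    )
    lo, hi = x.min() - 1.0, x.max() + 1.0
    if not (lo <= fit.pCa50 <= hi):
        raise RuntimeError(f"fitted pCa50 {fit.pCa50:.2f} outside data range ± 1")
    return fit


@dataclass
class ThreeStateFit:
    params: KineticParams
    se: dict[str, float]
    rss: float
    converged: bool
    kON: float

    @property
    def f(self):
        return self.params.f

    @property
    def g(self):
        return self.params.g

    @property
    def kOFF(self):
        return self.params.kOFF


def model_curves(params: KineticParams, pCa_grid) -> pd.DataFrame:
    """Force and kTR along a pCa grid under the 3-state model."""
    rows = []
    for p in np.asarray(pCa_grid, float):
        ss = steady_state(params, p)
        rows.append({"pCa": p, "force": ss["force"], "ktr": ktr(params, p)})
    return pd.DataFrame(rows)


def fit_three_state(
    data: pd.DataFrame,
    kON_fixed: float = REFERENCE_PARAMS.kON,
    activation: CaActivation | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> ThreeStateFit:
    """Joint weighted fit of force-pCa and force-kTR for (f, g, kOFF).

    kON is held fixed; rates are log-parameterized for positivity; residuals
    of each curve are normalized by that curve's data SD so force and kTR
    contribute comparably; >=8 seeded multi-starts with best-RSS selection.
    """
    act = activation or CaActivation()
    df = data.dropna(subset=["pCa", "force", "ktr"])
    pca_levels = np.unique(df["pCa"])
    if len(pca_levels) < 4:
        raise ValueError("need paired force/kTR at >=4 activation levels")
    x = df["pCa"].to_numpy(float)
    yF = df["force"].to_numpy(float)
    yK = df["ktr"].to_numpy(float)
    sF = max(float(np.std(yF)), 1e-9)
    sK = max(float(np.std(yK)), 1e-9)

    def resid(theta):
        f, g, koff = np.exp(theta)
        params = KineticParams(kON_fixed, koff, f, g, act)
        force_m = np.empty_like(x)
        ktr_m = np.empty_like(x)
        for i, p in enumerate(x):
            ss = steady_state(params, p)
            force_m[i] = ss["force"]
            ktr_m[i] = ktr(params, p)
        return np.concatenate([(force_m - yF) / sF, (ktr_m - yK) / sK])

    rng = np.random.default_rng(seed)
    k_scale = max(float(np.nanmax(yK)), 1.0)
    best = None
    diagnostics = []
    for istart in range(n_starts):
        f0 = k_scale * rng.uniform(0.3, 1.5)
        g0 = k_scale * rng.uniform(0.1, 1.0)
        koff0 = kON_fixed * rng.uniform(0.1, 2.0)
        theta0 = np.log([f0, g0, koff0])
        try:
            sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=4000)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append(str(exc))
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < float(np.sum(best.fun**2)) - 1e-12:
            best = sol
    if best is None:
        raise RuntimeError("all multi-starts failed: " + "; ".join(diagnostics))

    f, g, koff = np.exp(best.x)
    params = KineticParams(kON_fixed, koff, f, g, act)
    rss = float(np.sum(best.fun**2))
    # delta-method SEs on the natural scale from the log-scale Jacobian
    dof = max(len(best.fun) - 3, 1)
    s2 = rss / dof
    try:
        cov_log = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        se = {"f": f * se_log[0], "g": g * se_log[1], "kOFF": koff * se_log[2]}
    except np.linalg.LinAlgError:
        se = {"f": np.nan, "g": np.nan, "kOFF": np.nan}
    return ThreeStateFit(params=params, se=se, rss=rss, converged=bool(best.success), kON=kON_fixed)


def perturbation_envelope(
    fit: ThreeStateFit | KineticParams,
    fractions=(-0.03, -0.01, 0.0, 0.01, 0.03),
    pCa_grid=None,
) -> dict[float, pd.DataFrame]:
    """Force-kTR loci with all four rates jointly scaled by (1 + fraction).

    Mirrors the published sensitivity envelope around the best fit: joint
    +/-1% and +/-3% scalings bracketing the fitted curve.
    """
    params = fit.params if isinstance(fit, ThreeStateFit) else fit
    if pCa_grid is None:
        pCa_grid = np.linspace(7.0, 4.0, 25)
    return {
        float(fr): model_curves(params.scaled(1.0 + fr), pCa_grid)
        for fr in fractions
    }
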