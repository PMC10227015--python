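"""Assay computations: melt curves, enzyme kinetics, dose-response, ITC.

Implements the quantitative readouts of a binding/inhibition campaign:

* thermal shift assay: melting temperature Tm as the midpoint of a
  Boltzmann sigmoid fit to the fluorescence melt curve (fallback: argmax of
  the smoothed derivative), and the stabilization shift dTm = Tm(holo) -
  Tm(apo);
* coupled enzymatic assay: reaction velocity as the slope of the most
  linear contiguous stretch of the NADH fluorescence decay, normalized to a
  drug-free control (ratio > 1 activation, < 1 inhibition);
* dose-response: four-parameter logistic (4PL) IC50 with a technical floor
  set by the enzyme concentration - fitted values below the floor are
  reported censored ("< floor");
* isothermal titration calorimetry: nonlinear least-squares fit of the
  independent-sites isotherm, with one or two site classes (the two-site
  model matches biphasic thermograms).

Units are normalized internally: temperature degC, time s, concentration
nM (molar inside the ITC solver), enthalpy kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .errors import (FitError, NoBindingSignalError, NonLinearTraceError,
                     NoTransitionError)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    temperature: np.ndarray  # degC, strictly ascending
    fluorescence: np.ndarray  # a.u.
    label: str = "apo"

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.temperature.size < 20:
            raise ValueError("melt curve needs >= 20 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class KineticTrace:
    time: np.ndarray  # s
    fluorescence: np.ndarray  # a.u. (NADH signal)
    condition: str = "drug-free"

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.time.size < 10:
            raise ValueError("kinetic trace needs >= 10 points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class DoseResponse:
    concentrations: np.ndarray  # nM, > 0
    responses: np.ndarray  # % of control
    replicate_ids: Optional[Sequence] = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass
class ItcIsotherm:
    molar_ratios: np.ndarray  # cumulative [titrant]/[cell species]
    heats: np.ndarray  # kcal per mol of injectant
    cell_concentration_uM: float
    syringe_concentration_uM: float
    temperature_C: float = 25.0

    def __post_init__(self):
        self.molar_ratios = np.asarray(self.molar_ratios, float)
        self.heats = np.asarray(self.heats, float)
        if self.molar_ratios.size < 10:
            raise ValueError("need >= 10 injections")
        if self.cell_concentration_uM <= 0 or self.syringe_concentration_uM <= 0:
            raise ValueError("concentrations must be positive")


@dataclass
class TmResult:
    tm: float  # degC
    method: str  # "boltzmann" | "derivative"
    residual_norm: float = float("nan")
    params: Tuple[float, ...] = ()


@dataclass
class Velocity:
    slope: float  # signed, a.u./s
    magnitude: float  # |slope|
    window: Tuple[int, int] = (0, 0)
    r_squared: float = 1.0
    degenerate: bool = False


@dataclass
class InhibitionResult:
    ic50: float  # nM (the floor when censored)
    censored: bool
    floor: Optional[float]
    hill_slope: float
    residual_norm: float
    top: float = 100.0
    bottom: float = 0.0

    def report(self) -> str:
        return f"< {self.floor:g} nM" if self.censored else f"{self.ic50:g} nM"


@dataclass
class ItcSite:
    n: float  # stoichiometry (sites per cell-species molecule)
    kd_nM: float
    dH_kcal_mol: float


@dataclass
class ItcFitResult:
    sites: List[ItcSite]
    residual_norm: float
    indistinguishable: bool = False  # two-site CIs overlap on monophasic data


# ---------------------------------------------------------------------------
# thermal shift
# ---------------------------------------------------------------------------

def boltzmann(T, bottom, top, tm, slope):
    return bottom + (top - bottom) / (1.0 + np.exp((tm - T) / slope))


def melting_temperature(curve: MeltCurve) -> TmResult:
    """Tm as the Boltzmann-sigmoid midpoint of the melt transition.

    Falls back to the argmax of the smoothed dF/dT when the sigmoid fit
    fails; raises :class:`NoTransitionError` for flat curves.
    """
    T, F = curve.temperature, curve.fluorescence
    amplitude = float(F.max() - F.min())
    scale = max(abs(F).max(), 1.0)
    if amplitude < 1e-9 * scale:
        raise NoTransitionError(f"no melt transition in curve {curve.label!r}")
    # derivative estimate (also the fallback)
    dF = np.gradient(F, T)
    kernel = np.ones(5) / 5.0
    dFs = np.convolve(dF, kernel, mode="same")
    t_deriv = float(T[int(np.argmax(dFs))])
    if np.max(dFs) <= 1e-9 * scale:
        raise NoTransitionError(f"no rising transition in curve {curve.label!r}")
    p0 = (float(F.min()), float(F.max()), t_deriv, 1.0)
    try:
        popt, _ = optimize.curve_fit(boltzmann, T, F, p0=p0, maxfev=10000)
        bottom, top, tm, slope = popt
        resid = float(np.linalg.norm(boltzmann(T, *popt) - F))
        if slope <= 0 or not (T.min() - 5 <= tm <= T.max() + 5):
            raise RuntimeError("implausible fit")
        return TmResult(float(tm), "boltzmann", resid, tuple(float(x) for x in popt))
    except Exception:
        return TmResult(t_deriv, "derivative")


def delta_tm(holo_tm: float, apo_tm: float) -> float:
    """Signed thermal shift dTm = Tm(holo) - Tm(apo), degC."""
    if not (np.isfinite(holo_tm) and np.isfinite(apo_tm)):
        raise ValueError("Tm values must be finite")
    return float(holo_tm) - float(apo_tm)


# ---------------------------------------------------------------------------
# enzyme kinetics
# ---------------------------------------------------------------------------

def _linfit_stats(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Slope and R^2 of an ordinary least-squares line (R^2=1 for flat y)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    if syy < 1e-12 * max(1.0, ym * ym):
        return slope, 1.0  # zero-variance window: perfectly linear, slope ~0
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, r2


def linear_range_velocity(trace: KineticTrace, r2_threshold: float = 0.99,
                          min_fraction: float = 0.3) -> Velocity:
    """Slope of the most linear contiguous window (R^2 >= threshold).

    Among windows of at least ``min_fraction`` of the points whose linear
    fit reaches the R^2 threshold, the window with the highest R^2 (rounded
    to 1e-6, so near-ties resolve by length) wins; ties then break toward
    longer windows and earlier starts.  A globally flat trace is accepted as
    velocity 0 and flagged degenerate; a trace with no qualifying window
    raises :class:`NonLinearTraceError`.
    """
    t, f = trace.time, trace.fluorescence
    n = t.size
    min_len = max(int(np.ceil(min_fraction * n)), 3)
    best = None  # (round(r2), length, -start, slope, r2, window)
    for start in range(0, n - min_len + 1):
        for stop in range(start + min_len, n + 1):
            slope, r2 = _linfit_stats(t[start:stop], f[start:stop])
            if r2 >= r2_threshold:
                cand = (round(r2, 6), stop - start, -start, slope, r2,
                        (start, stop))
                if best is None or cand[:3] > best[:3]:
                    best = cand
    if best is None:
        raise NonLinearTraceError(
            f"no window of >= {min_len} points reaches R^2 {r2_threshold}")
    _, length, _, slope, r2, window = best
    span = float(f.max() - f.min())
    degenerate = span < 1e-9 * max(1.0, abs(f).max())
    if degenerate:
        slope = 0.0
    return Velocity(slope=float(slope), magnitude=abs(float(slope)),
                    window=window, r_squared=float(r2), degenerate=degenerate)


def normalized_activity(v_compound: Velocity | float,
                        v_control: Velocity | float) -> float:
    """Velocity ratio vs the drug-free control (>1 activation, <1 inhibition)."""
    vc = v_compound.magnitude if isinstance(v_compound, Velocity) else float(v_compound)
    v0 = v_control.magnitude if isinstance(v_control, Velocity) else float(v_control)
    if v0 == 0:
        raise ValueError("control velocity is zero")
    return vc / v0


# ---------------------------------------------------------------------------
# dose-response (4PL)
# ---------------------------------------------------------------------------

def four_pl(conc, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def fit_ic50(dr: DoseResponse, floor: Optional[float] = None,
             top_bottom_bounds: Tuple[float, float] = (0.0, 120.0)) -> InhibitionResult:
    """4PL least-squares IC50 (nM) with optional technical-floor censoring.

    The floor is the lowest resolvable IC50 (set by the enzyme concentration
    in enzymatic assays); a fitted IC50 below it is reported as "< floor".
    Top/bottom are constrained to ``top_bottom_bounds`` (percent of control).
    """
    c, r = dr.concentrations, dr.responses
    span = float(r.max() - r.min())
    if span < 40.0:
        raise FitError("responses span less than 40% of the dynamic range",
                       {"span": span})
    lo, hi = top_bottom_bounds
    p0 = (max(lo, float(r.min())), min(hi, float(r.max())),
          float(np.exp(np.mean(np.log(c)))), 1.0)
    bounds = ([lo, lo, float(c.min()) / 1e3, 0.1],
              [hi, hi, float(c.max()) * 1e3, 10.0])
    try:
        popt, _ = optimize.curve_fit(four_pl, c, r, p0=p0, bounds=bounds,
                                     maxfev=20000)
    except Exception as exc:
        raise FitError(f"4PL fit failed to converge: {exc}") from exc
    bottom, top, ic50, hill = (float(x) for x in popt)
    resid = float(np.linalg.norm(four_pl(c, *popt) - r))
    censored = floor is not None and ic50 < floor
    return InhibitionResult(
        ic50=float(floor) if censored else ic50, censored=censored,
        floor=floor, hill_slope=hill, residual_norm=resid,
        top=top, bottom=bottom)


# ---------------------------------------------------------------------------
# ITC: independent-sites isotherm
# ---------------------------------------------------------------------------

def itc_injection_heats(molar_ratios: np.ndarray, cell_conc_M: float,
                        sites: Sequence[ItcSite]) -> np.ndarray:
    """Forward model: heat per mole of injectant at each injection.

    Independent-sites isotherm with the cell species carrying the sites and
    the injectant titrated in; the cell concentration is treated as constant
    over the titration (injection volumes are small relative to the cell).
    For reverse titrations the cell/syringe roles are simply swapped by the
    caller - the binding polynomial is symmetric in that exchange.
    """
    ratios = np.asarray(molar_ratios, float)
    M0 = float(cell_conc_M)
    kds = np.array([s.kd_nM * 1e-9 for s in sites])  # molar
    ns = np.array([s.n for s in sites])
    dhs = np.array([s.dH_kcal_mol for s in sites])

    def free_titrant(x_total: float) -> float:
        if x_total <= 0:
            return 0.0
        f = lambda x: x + M0 * np.sum(ns * x / (kds + x)) - x_total
        return optimize.brentq(f, 0.0, x_total, xtol=1e-18, rtol=1e-14)

    theta_prev = np.zeros(len(sites))
    x_prev = 0.0
    out = np.empty(ratios.size)
    for i, r in enumerate(ratios):
        x_total = r * M0
        x_free = free_titrant(x_total)
        theta = x_free / (kds + x_free)
        d_bound = M0 * ns * (theta - theta_prev)
        d_x = x_total - x_prev
        out[i] = float(np.sum(dhs * d_bound) / d_x) if d_x > 0 else 0.0
        theta_prev, x_prev = theta, x_total
    return out


def _pack(sites: Sequence[ItcSite]) -> np.ndarray:
    return np.array([v for s in sites for v in (s.n, np.log10(s.kd_nM), s.dH_kcal_mol)])


def _unpack(vec: np.ndarray) -> List[ItcSite]:
    return [ItcSite(n=float(vec[i]), kd_nM=float(10 ** vec[i + 1]),
                    dH_kcal_mol=float(vec[i + 2]))
            for i in range(0, len(vec), 3)]


def itc_fit(iso: ItcIsotherm, model: str = "two_site") -> ItcFitResult:
    """Nonlinear least-squares fit of the independent-sites ITC isotherm.

    ``model`` is ``one_site`` or ``two_site``.  The two-site fit is seeded
    from the one-site solution (plus a weak second site), so its residual
    never exceeds the nested one-site residual.  When the two fitted
    dissociation constants are statistically indistinguishable (overlapping
    approximate confidence intervals on log KD), the result is flagged.
    """
    if model not in ("one_site", "two_site"):
        raise ValueError(f"unknown ITC model {model!r}")
    heats = iso.heats
    if np.max(np.abs(heats)) < 1e-9:
        raise NoBindingSignalError("all injection heats are zero")
    M0 = iso.cell_concentration_uM * 1e-6

    def residuals(vec):
        sites = _unpack(vec)
        return itc_injection_heats(iso.molar_ratios, M0, sites) - heats

    dh0 = float(heats[np.argmax(np.abs(heats[:3]))]) if heats.size >= 3 else float(heats[0])
    kd0_log = np.log10(max(iso.cell_concentration_uM * 1e3 / 10.0, 1.0))  # ~M0/10 in nM
    one0 = _pack([ItcSite(1.0, 10 ** kd0_log, dh0)])
    lb1 = [0.05, np.log10(1e-3), -100.0]
    ub1 = [10.0, np.log10(1e9), 100.0]

    def solve(x0, lb, ub):
        return optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                      xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                      max_nfev=5000)

    res1 = solve(one0, lb1, ub1)
    if model == "one_site":
        return ItcFitResult(sites=_unpack(res1.x),
                            residual_norm=float(np.linalg.norm(res1.fun)))

    s1 = _unpack(res1.x)[0]
    # second site seeded weak and 100x looser; small dH so the start point
    # reproduces (approximately) the one-site optimum
    two0 = _pack([s1, ItcSite(1.0, s1.kd_nM * 100.0, dh0 * 0.1)])
    res2 = solve(two0, lb1 * 2, ub1 * 2)
    if float(np.linalg.norm(res2.fun)) > float(np.linalg.norm(res1.fun)):
        # keep the nested optimum if the larger model failed to improve
        res2_x = np.concatenate([res1.x, _pack([ItcSite(1.0, s1.kd_nM * 100.0, 0.0)])[:3]])
        res2 = solve(res2_x, lb1 * 2, ub1 * 2)
    sites = _unpack(res2.x)
    resid = float(np.linalg.norm(res2.fun))

    # approximate CIs on log10 KD from the Jacobian
    indistinct = False
    try:
        J = res2.jac
        dof = max(heats.size - res2.x.size, 1)
        s2 = resid ** 2 / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.abs(np.diag(cov)))
        lk1, lk2 = res2.x[1], res2.x[4]
        se1, se2 = se[1], se[4]
        lo1, hi1 = lk1 - 2 * se1, lk1 + 2 * se1
        lo2, hi2 = lk2 - 2 * se2, lk2 + 2 * se2
        indistinct = max(lo1, lo2) <= min(hi1, hi2)
    except Exception:
        pass
    sites = sorted(sites, key=lambda s: s.kd_nM)
    return ItcFitResult(sites=sites, residual_norm=resid,
                        indistinguishable=indistinct)
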