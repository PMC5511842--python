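"""One-tissue two-rate-constant (1T2K) compartment model.

The model describes reversible tracer exchange between arterial plasma and a
single tissue compartment::

    dC_t/dt = K1 * C_p(t) - k2 * C_t(t)

with influx rate ``K1`` (mL·cm⁻³·min⁻¹), efflux rate ``k2`` (min⁻¹) and
distribution volume ``VT = K1/k2``.  The measurable PET signal adds a
fractional blood-volume term::

    C_pet(t) = (1 - Vb) * C_t(t) + Vb * C_wb(t - Δ)

where ``C_wb`` is the whole-blood curve and ``Δ`` a short delay (seconds)
between the arterial sampling site and the brain capillaries.  Fitting is by
weighted least squares on frame-averaged values, with the delay selected over
a discrete 1 s grid.

Because the model is linear in ``K1`` (and in ``Vb``), the nonlinear search
is reduced to a one-dimensional profile over ``k2`` (variable projection):
for each candidate ``k2`` the optimal linear coefficients have a closed form,
which makes the fit deterministic and free of multi-start heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve


class FitError(RuntimeError):
    """Raised when the kinetic fit cannot produce a finite solution."""


@dataclass(frozen=True)
class KineticParams:
    """1T2K parameter set.

    Attributes
    ----------
    K1 : float
        Plasma-to-tissue influx rate, mL·cm⁻³·min⁻¹.
    k2 : float
        Tissue-to-plasma efflux rate, min⁻¹.
    Vb : float
        Fractional blood volume, unitless in [0, 1).
    delay_s : float
        Input-function delay in seconds.
    """

    K1: float
    k2: float
    Vb: float = 0.05
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError(f"K1 must be >= 0, got {self.K1}")
        if not (0 <= self.Vb < 1):
            raise ValueError(f"Vb must be in [0, 1), got {self.Vb}")

    @property
    def VT(self) -> float:
        """Distribution volume K1/k2 (0 when K1 = 0)."""
        if self.K1 == 0:
            return 0.0
        if self.k2 <= 0:
            raise ValueError("VT undefined for k2 <= 0 with K1 > 0")
        return self.K1 / self.k2


@dataclass(frozen=True)
class FitResult:
    """Kinetic fit output: best parameters plus diagnostics."""

    params: KineticParams
    wrss: float
    wrss_by_delay: dict = field(default_factory=dict)

    @property
    def VT(self) -> float:
        return self.params.VT


def metabolite_correct(c_plasma_total: np.ndarray, parent_fraction: np.ndarray) -> np.ndarray:
    """Parent-tracer plasma curve: total plasma activity times parent fraction.

    Both curves must share the same time grid; the fraction must lie in [0, 1].
    """
    c_plasma_total = np.asarray(c_plasma_total, dtype=float)
    parent_fraction = np.asarray(parent_fraction, dtype=float)
    if c_plasma_total.shape != parent_fraction.shape:
        raise ValueError("curves must share a time grid")
    if np.any(parent_fraction < 0) or np.any(parent_fraction > 1):
        raise ValueError("parent_fraction must lie in [0, 1]")
    return c_plasma_total * parent_fraction


def _shift_curve(t_min: np.ndarray, curve: np.ndarray, delay_s: float) -> np.ndarray:
    """Delay a sampled curve by ``delay_s`` seconds (zero before support)."""
    if delay_s == 0:
        return curve
    return np.interp(t_min - delay_s / 60.0, t_min, curve, left=0.0, right=curve[-1])


def _conv_exp(t_min: np.ndarray, c_in: np.ndarray, k2: float) -> np.ndarray:
    """Trapezoid-rule causal convolution of ``c_in`` with exp(-k2 t)."""
    n = t_min.size
    dt = t_min[1] - t_min[0]
    kern = np.exp(-k2 * (t_min - t_min[0]))
    full = fftconvolve(c_in, kern)[:n] * dt
    # trapezoid end-point correction: full rectangle sum -> trapezoid
    full -= 0.5 * dt * (c_in[0] * kern + c_in * kern[0])
    return full


def _frame_average(t_min: np.ndarray, curve: np.ndarray, schedule) -> np.ndarray:
    """Average a finely sampled curve over each frame interval."""
    if schedule.end_min[-1] > t_min[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond input-curve support")
    out = np.empty(schedule.n_frames)
    for i, (a, b) in enumerate(zip(schedule.start_min, schedule.end_min)):
        sel = (t_min >= a - 1e-9) & (t_min <= b + 1e-9)
        ts, cs = t_min[sel], curve[sel]
        out[i] = np.trapezoid(cs, ts) / (ts[-1] - ts[0])
    return out


def _check_grid(t_min: np.ndarray) -> None:
    dt = np.diff(t_min)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("input curves must be on a uniform time grid")
    if dt[0] > 1.0 / 60.0 + 1e-9:
        raise ValueError("input curves must be sampled at <= 1 s resolution")


def tissue_response(params: KineticParams, inputs, *, with_blood: bool = True) -> np.ndarray:
    """Continuous-time model prediction C_pet(t) on the input time grid."""
    t = inputs.t_min
    _check_grid(t)
    cp = _shift_curve(t, inputs.c_plasma_parent, params.delay_s)
    ct = params.K1 * _conv_exp(t, cp, params.k2) if params.K1 > 0 else np.zeros_like(t)
    if not with_blood or params.Vb == 0:
        return ct
    cwb = _shift_curve(t, inputs.c_wholeblood, params.delay_s)
    return (1.0 - params.Vb) * ct + params.Vb * cwb


def model_tac(params: KineticParams, inputs, schedule) -> np.ndarray:
    """Frame-averaged 1T2K prediction for one region.

    Parameters
    ----------
    params : KineticParams
    inputs : InputFunctionSet
        Must cover the schedule on a uniform grid of at most 1 s.
    schedule : FrameSchedule

    Returns
    -------
    ndarray of per-frame mean concentrations (same units as the input curves).
    """
    return _frame_average(inputs.t_min, tissue_response(params, inputs), schedule)


def _profile_linear(
    y: np.ndarray,
    basis: np.ndarray,
    cwb_frames: np.ndarray,
    w: np.ndarray,
    vb_fixed: float | None,
):
    """Optimal (K1, Vb) for a fixed k2 basis, by weighted linear LS.

    ``basis`` is the frame-averaged unit-K1 tissue response (no blood-volume
    factor).  With ``a = K1 (1 - Vb)`` the model is
    ``y = a * basis + Vb * cwb_frames``; both coefficients are linear.  When
    ``vb_fixed`` is given only ``a`` is free.  Coefficients are clipped to
    their physical ranges.
    """
    if vb_fixed is not None:
        target = y - vb_fixed * cwb_frames
        denom = np.sum(w * basis * basis)
        a = np.sum(w * basis * target) / denom if denom > 0 else 0.0
        a = max(a, 0.0)
        resid = target - a * basis
        vb = vb_fixed
    else:
        X = np.column_stack([basis, cwb_frames])
        Xw = X * w[:, None]
        try:
            coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        except np.linalg.LinAlgError:
            coef = np.array([0.0, 0.0])
        a, vb = coef
        a = max(a, 0.0)
        vb = float(np.clip(vb, 0.0, 0.95))
        resid = y - a * basis - vb * cwb_frames
    k1 = a / (1.0 - vb)
    wrss = float(np.sum(w * resid * resid))
    return k1, vb, wrss


def fit_1t2k(
    tac: np.ndarray,
    inputs,
    schedule,
    *,
    delay_grid_s: Sequence[float] = (1, 2, 3, 4, 5),
    weights: np.ndarray | None = None,
    vb_fixed: float | None = 0.05,
    k2_bounds: tuple[float, float] = (1e-3, 2.0),
    k2_grid_size: int = 40,
) -> FitResult:
    """Fit the 1T2K model to a regional TAC.

    For each candidate delay the weighted residual sum of squares is profiled
    over ``k2`` (coarse logarithmic grid refined by bounded Brent search);
    ``K1`` (and optionally ``Vb``) are solved in closed form at every ``k2``.
    The returned delay minimises WRSS, with ties broken toward the smaller
    delay.  Default weights are the frame durations.

    Raises
    ------
    FitError
        If no delay yields a finite objective.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.size != schedule.n_frames:
        raise ValueError("TAC length does not match schedule")
    if tac.size < 6:
        raise ValueError("at least 6 frames are required for a 1T2K fit")
    w = schedule.durations_min if weights is None else np.asarray(weights, dtype=float)
    t = inputs.t_min
    _check_grid(t)

    lo, hi = k2_bounds
    k2_grid = np.geomspace(lo, hi, k2_grid_size)
    best = None
    wrss_by_delay: dict[float, float] = {}

    for delay in delay_grid_s:
        cp = _shift_curve(t, inputs.c_plasma_parent, delay)
        cwb = _shift_curve(t, inputs.c_wholeblood, delay)
        cwb_frames = _frame_average(t, cwb, schedule)

        def objective(k2: float) -> tuple[float, float, float]:
            basis = _frame_average(t, _conv_exp(t, cp, k2), schedule)
            k1, vb, wrss = _profile_linear(tac, basis, cwb_frames, w, vb_fixed)
            return wrss, k1, vb

        vals = [objective(k2)[0] for k2 in k2_grid]
        i0 = int(np.argmin(vals))
        blo = k2_grid[max(i0 - 1, 0)]
        bhi = k2_grid[min(i0 + 1, k2_grid.size - 1)]
        if blo < bhi:
            res = minimize_scalar(lambda k2: objective(k2)[0], bounds=(blo, bhi), method="bounded")
            k2_best = float(res.x)
            # never accept a refinement worse than the grid minimum
            if res.fun > vals[i0]:
                k2_best = float(k2_grid[i0])
        else:
            k2_best = float(k2_grid[i0])
        wrss, k1, vb = objective(k2_best)
        wrss_by_delay[float(delay)] = wrss
        if np.isfinite(wrss) and (best is None or wrss < best[0] - 1e-12):
            best = (wrss, k1, k2_best, vb, float(delay))

    if best is None:
        raise FitError(f"1T2K fit failed at all delays; objectives: {wrss_by_delay}")
    wrss, k1, k2, vb, delay = best
    params = KineticParams(K1=k1, k2=k2, Vb=vb, delay_s=delay)
    return FitResult(params=params, wrss=wrss, wrss_by_delay=wrss_by_delay)


def fits_to_frame(fits: dict[str, FitResult]):
    """Tabulate a region->FitResult mapping as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for region, fr in fits.items():
        p = fr.params
        rows.append(
            dict(region=region, K1=p.K1, k2=p.k2, Vb=p.Vb, delay_s=p.delay_s, VT=p.VT, wrss=fr.wrss)
        )
    return pd.DataFrame(rows)
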