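"""Kinetic model of reporter expression from transfected mRNA.

A linear three-compartment cascade in time t (minutes) after transfection:

    d[mRNA]/dt     = -lambda_RNA * [mRNA]
    d[inactive]/dt =  k_trans * [mRNA] - k_mat * [inactive]
    d[fluor]/dt    =  k_mat * [inactive] - lambda_fluor * [fluor]

with initial condition ([mRNA], [inactive], [fluor]) = (m0, 0, 0): mRNA
decays first-order, is translated into immature (non-fluorescent) protein,
which matures into the observed fluorophore and is finally degraded.  The
observable signal is [fluor](t).

The exact solution is a sum of up to three exponentials; the fluorophore
compartment equals ``m0 * k_trans * k_mat`` times the second divided
difference of exp(-x t) on the nodes (lambda_RNA, k_mat, lambda_fluor), which
makes the shape symmetric under any permutation of the three rates -- the
identifiability hazard the hierarchical fit must manage.  Near-coincident
rates are evaluated with the confluent limit forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "StateTrajectory",
    "simulate_closed_form",
    "simulate_numeric",
    "half_life",
    "rate_from_half_life",
    "DEGENERATE_RTOL",
]

LN2 = float(np.log(2.0))

#: Two rates closer than this (relative) are treated as equal and evaluated
#: with the confluent formulas; the generic three-pole formula is numerically
#: unstable below this gap.
DEGENERATE_RTOL = 1e-8


@dataclass(frozen=True)
class KineticParams:
    """Rates of the expression cascade (all 1/min) plus initial mRNA amount.

    m0 is on an arbitrary dimensionless scale; only the product
    ``m0 * k_trans`` is identifiable from fluorescence, so fits hold m0 = 1.
    """

    lambda_rna: float
    k_trans: float
    k_mat: float
    lambda_fluor: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("lambda_rna", "k_trans", "k_mat", "lambda_fluor", "m0"):
            value = getattr(self, attr)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{attr} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class StateTrajectory:
    """Aligned (time, mRNA, inactive protein, fluorophore) series."""

    times: np.ndarray
    mrna: np.ndarray
    inactive: np.ndarray
    fluor: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "mrna": self.mrna,
                "inactive": self.inactive,
                "fluor": self.fluor,
            }
        )


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("negative time")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= DEGENERATE_RTOL * max(abs(a), abs(b))


def _dd1(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """(exp(-a t) - exp(-b t)) / (b - a), confluent limit t exp(-a t)."""
    if _close(a, b):
        r = 0.5 * (a + b)
        return t * np.exp(-r * t)
    return (np.exp(-a * t) - np.exp(-b * t)) / (b - a)


def _dd2_confluent(t: np.ndarray, double: float, single: float) -> np.ndarray:
    """Second divided difference of exp(-x t) with a double node."""
    gap = single - double
    return (np.exp(-single * t) - np.exp(-double * t) * (1.0 - gap * t)) / (gap * gap)


def _dd2(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Second divided difference of exp(-x t) on nodes (a, b, c).

    Symmetric in its three rate arguments; equals
    sum_i exp(-x_i t) / prod_{j != i} (x_j - x_i).
    """
    lo, mid, hi = sorted((a, b, c))
    low_pair = _close(lo, mid)
    high_pair = _close(mid, hi)
    if low_pair and high_pair:
        r = (lo + mid + hi) / 3.0
        return 0.5 * t * t * np.exp(-r * t)
    if low_pair:
        return _dd2_confluent(t, 0.5 * (lo + mid), hi)
    if high_pair:
        return _dd2_confluent(t, 0.5 * (mid + hi), lo)
    ea, eb, ec = np.exp(-lo * t), np.exp(-mid * t), np.exp(-hi * t)
    return (
        ea / ((mid - lo) * (hi - lo))
        + eb / ((lo - mid) * (hi - mid))
        + ec / ((lo - hi) * (mid - hi))
    )


def fluor_shape(times: np.ndarray, lambda_rna: float, k_mat: float, lambda_fluor: float) -> np.ndarray:
    """Fluorophore trajectory for k_trans = m0 = 1 (the fit's unit shape)."""
    return k_mat * _dd2(times, lambda_rna, k_mat, lambda_fluor)


def simulate_closed_form(params: KineticParams, times) -> StateTrajectory:
    """Evaluate the exact solution of the cascade at the given times (min)."""
    t = _check_times(times)
    a, b, c = params.lambda_rna, params.k_mat, params.lambda_fluor
    amp = params.m0 * params.k_trans
    mrna = params.m0 * np.exp(-a * t)
    inactive = amp * _dd1(t, a, b)
    fluor = amp * b * _dd2(t, a, b, c)
    # the divided differences vanish analytically at t = 0; enforce the
    # initial condition exactly instead of leaving cancellation residue
    at_zero = t == 0.0
    if np.any(at_zero):
        inactive = np.where(at_zero, 0.0, inactive)
        fluor = np.where(at_zero, 0.0, fluor)
    return StateTrajectory(t, mrna, inactive, fluor)


def simulate_numeric(
    params: KineticParams, times, rtol: float = 1e-10, atol: float = 1e-14
) -> StateTrajectory:
    """Integrate the cascade ODEs with adaptive step control.

    Serves as an independent oracle for :func:`simulate_closed_form`; the two
    agree to <= 1e-6 relative error on non-degenerate rates.
    """
    t = _check_times(times)
    a, kt, b, c, m0 = (
        params.lambda_rna,
        params.k_trans,
        params.k_mat,
        params.lambda_fluor,
        params.m0,
    )

    def rhs(_t, y):
        m, p, f = y
        return [-a * m, kt * m - b * p, b * p - c * f]

    t_end = float(t[-1])
    if t_end == 0.0:
        zeros = np.zeros_like(t)
        return StateTrajectory(t, np.full_like(t, m0), zeros, zeros)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [m0, 0.0, 0.0],
        method="DOP853",
        t_eval=t,
        rtol=rtol,
        atol=atol * max(m0, m0 * kt),
        # cap the step: the high-order dense output used for t_eval loses
        # several digits over the very large steps this smooth decay allows
        max_step=t_end / 128.0,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return StateTrajectory(t, sol.y[0], sol.y[1], sol.y[2])


def half_life(rate: float) -> float:
    """Half-life (min) of a first-order process: t_0.5 = ln(2)/rate."""
    if not np.isfinite(rate) or rate <= 0:
        raise ValueError(f"rate must be strictly positive, got {rate!r}")
    return LN2 / rate


def rate_from_half_life(t_half: float) -> float:
    """Inverse of :func:`half_life`: rate = ln(2)/t_0.5."""
    if not np.isfinite(t_half) or t_half <= 0:
        raise ValueError(f"half-life must be strictly positive, got {t_half!r}")
    return LN2 / t_half
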