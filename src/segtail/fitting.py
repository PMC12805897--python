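"""Hierarchical global/local fitting of the expression cascade.

Two nested levels, both minimizing mean absolute error (MAE):

* global -- one (k_mat, lambda_fluor) pair per cell line, found by a
  derivative-free multi-start Nelder-Mead search over the log-rates that
  minimizes the summed MAE of all time courses in that cell line;
* local  -- per time course (variant x replicate), (lambda_RNA, k_trans)
  given the candidate global rates.

The local problem is solved exactly in the scale parameter: for fixed
lambda_RNA the fluorophore curve is ``k_trans * s(t)`` with a known unit
shape s, and the MAE-optimal k_trans is the s-weighted median of
signal/shape ratios (for the optional L2 objective, a ratio of inner
products).  What remains is a 1-D search over log lambda_RNA, run from
multiple bracketed starts with golden-section refinement -- deterministic,
with no random seeds anywhere in the fitting path.

Identifiability.  The fluorophore shape is symmetric under permutation of
the three rates, and because k_trans is profiled out, the outer objective is
*exactly* symmetric in (k_mat, lambda_fluor).  The swap is resolved by the
reporting convention k_mat >= lambda_fluor (maturation is faster than
degradation for destabilized reporters).  Permutations involving lambda_RNA
are broken by contrast: lambda_RNA is local while the other two rates are
shared, so datasets with >= 2 variants of different mRNA stability pin the
roles.  Single-variant datasets are fit but flagged non-identifiable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import TimeCourse
from .kinetics import DEGENERATE_RTOL, LN2, _dd2, half_life

__all__ = [
    "FitConfig",
    "LocalFit",
    "HierarchicalFitResult",
    "FitError",
    "fit_local",
    "fit_global",
    "aggregate_replicates",
]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


class FitError(RuntimeError):
    """Raised when no start of a fit converges to a finite objective."""


@dataclass(frozen=True)
class FitConfig:
    """Bounds, starts and tolerances of the hierarchical fit.

    Half-life bounds keep the time scales apart: the mRNA decay rate is
    searched between 60 and 3000 min half-life, the two protein rates between
    30 and 1000 min.  Starts are expressed as half-lives in minutes.
    """

    rna_half_life_bounds: tuple[float, float] = (60.0, 3000.0)
    protein_half_life_bounds: tuple[float, float] = (30.0, 1000.0)
    rna_start_half_lives: tuple[float, ...] = (100.0, 400.0, 1600.0)
    k_mat_start_half_lives: tuple[float, ...] = (40.0, 80.0, 160.0)
    lambda_fluor_start_half_lives: tuple[float, ...] = (100.0, 200.0, 400.0)
    inner_objective: str = "mae"  # "mae" or "l2"
    fit_offset: bool = False
    inner_bracket_factor: float = 4.0
    inner_log_tol: float = 1e-4
    outer_xatol: float = 1e-4
    outer_fatol: float = 1e-9
    outer_maxfev: int = 250

    def __post_init__(self) -> None:
        if self.inner_objective not in ("mae", "l2"):
            raise ValueError("inner_objective must be 'mae' or 'l2'")
        for lo, hi in (self.rna_half_life_bounds, self.protein_half_life_bounds):
            if not 0 < lo < hi:
                raise ValueError("half-life bounds must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class LocalFit:
    """Per-curve estimates at fixed global rates."""

    lambda_rna: float
    k_trans: float
    mae: float  # mean absolute error at the returned parameters
    objective: float  # value of the configured inner objective
    offset: float = 0.0


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    idx = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(v[min(idx, v.size - 1)])


def _profile_scale(
    y: np.ndarray, s: np.ndarray, objective: str
) -> tuple[float, float]:
    """Optimal scale k for y ~ k*s and the objective value at it."""
    if objective == "mae":
        k = _weighted_median(y / s, s)
        obj = float(np.mean(np.abs(y - k * s)))
    else:
        k = float(np.dot(y, s) / np.dot(s, s))
        obj = float(np.mean((y - k * s) ** 2))
    return k, obj


def _golden_min(
    f: Callable[[float], float], lo: float, hi: float, tol: float
) -> None:
    """Golden-section descent on [lo, hi]; results are observed through f."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)


def _shape_cached(
    t: np.ndarray,
    a: float,
    b: float,
    c: float,
    eb: np.ndarray,
    ec: np.ndarray,
) -> np.ndarray:
    """Unit fluorophore shape reusing precomputed exp(-b t), exp(-c t)."""
    scale = max(a, b, c)
    if min(abs(a - b), abs(a - c), abs(b - c)) <= 10.0 * DEGENERATE_RTOL * scale:
        return b * _dd2(t, a, b, c)
    ea = np.exp(-a * t)
    return b * (
        ea / ((b - a) * (c - a))
        + eb / ((a - b) * (c - b))
        + ec / ((a - c) * (b - c))
    )


def _fit_local_core(
    t: np.ndarray,
    y: np.ndarray,
    k_mat: float,
    lambda_fluor: float,
    starts: Sequence[float],
    config: FitConfig,
    eb: np.ndarray | None = None,
    ec: np.ndarray | None = None,
) -> LocalFit:
    if eb is None:
        eb = np.exp(-k_mat * t)
    if ec is None:
        ec = np.exp(-lambda_fluor * t)
    lo_rate = LN2 / config.rna_half_life_bounds[1]
    hi_rate = LN2 / config.rna_half_life_bounds[0]
    objective = config.inner_objective
    offset_grid: Sequence[float]
    if config.fit_offset:
        ymax = float(np.max(y))
        offset_grid = tuple(np.linspace(0.0, 0.5 * ymax, 6))
    else:
        offset_grid = (0.0,)

    best: list = [np.inf, None, None, None]  # obj, a, k, offset

    def evaluate(log_a: float) -> float:
        a = math.exp(log_a)
        s = _shape_cached(t, a, k_mat, lambda_fluor, eb, ec)
        if not np.all(np.isfinite(s)) or np.max(s) <= 0.0:
            return np.inf
        local_best = np.inf
        for off in offset_grid:
            k, obj = _profile_scale(y - off, s, objective)
            if k <= 0.0:
                continue
            if objective == "mae":
                obj = float(np.mean(np.abs(y - off - k * s)))
            if obj < local_best:
                local_best = obj
            if obj < best[0]:
                best[0], best[1], best[2], best[3] = obj, a, k, off
        return local_best

    log_lo, log_hi = math.log(lo_rate), math.log(hi_rate)
    span = math.log(config.inner_bracket_factor)
    for start in starts:
        if not np.isfinite(start) or start <= 0:
            raise ValueError(f"invalid lambda_RNA start {start!r}")
        ls = min(max(math.log(start), log_lo), log_hi)
        lo = max(log_lo, ls - span)
        hi = min(log_hi, ls + span)
        if hi - lo < config.inner_log_tol:
            evaluate(0.5 * (lo + hi))
            continue
        _golden_min(evaluate, lo, hi, config.inner_log_tol)

    if best[1] is None:
        raise FitError(
            "no start converged to a finite objective "
            f"(starts={list(starts)}, k_mat={k_mat}, lambda_fluor={lambda_fluor})"
        )
    a, k, off = best[1], best[2], best[3]
    s = _shape_cached(t, a, k_mat, lambda_fluor, eb, ec)
    mae = float(np.mean(np.abs(y - off - k * s)))
    return LocalFit(lambda_rna=a, k_trans=k, mae=mae, objective=best[0], offset=off)


def fit_local(
    tc: TimeCourse,
    k_mat: float,
    lambda_fluor: float,
    starts: Sequence[float] | None = None,
    config: FitConfig | None = None,
) -> LocalFit:
    """Fit (lambda_RNA, k_trans) for one time course at fixed global rates.

    ``starts`` are initial guesses for lambda_RNA (1/min); each start is
    refined by golden-section search on a bracket of +/- one
    ``inner_bracket_factor`` decade-fraction around it, clipped to the
    configured bounds, and the best refinement wins.  Adding starts can only
    add candidates, so the returned objective never worsens.  Deterministic.
    """
    config = config or FitConfig()
    if k_mat <= 0 or lambda_fluor <= 0:
        raise ValueError("global rates must be strictly positive")
    y = tc.signal
    if not np.any(y > 0):
        raise FitError("all-zero signal: no expression to fit")
    if starts is None:
        starts = tuple(LN2 / h for h in config.rna_start_half_lives)
    if len(tuple(starts)) == 0:
        raise ValueError("at least one start is required")
    return _fit_local_core(tc.times, y, k_mat, lambda_fluor, tuple(starts), config)


@dataclass(frozen=True)
class HierarchicalFitResult:
    """Shared protein rates per cell line plus per-variant local estimates."""

    cell_line: str
    k_mat_hat: float
    lambda_fluor_hat: float
    per_variant: pd.DataFrame  # variant, replicate, lambda_rna_hat, k_trans_hat, rna_half_life, mae
    replicate_summary: pd.DataFrame
    total_mae: float
    identifiable: bool
    config: FitConfig

    @property
    def protein_half_life(self) -> float:
        return half_life(self.lambda_fluor_hat)

    @property
    def maturation_half_life(self) -> float:
        return half_life(self.k_mat_hat)


def aggregate_replicates(per_variant: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1) of half-life and k_trans per variant.

    With a single replicate the SD is reported as 0 and flagged.
    """
    required = {"variant", "rna_half_life", "k_trans_hat"}
    missing = required - set(per_variant.columns)
    if missing:
        raise ValueError(f"per-variant table is missing columns: {sorted(missing)}")
    rows = []
    for variant, grp in per_variant.groupby("variant", sort=True):
        n = len(grp)
        rows.append(
            {
                "variant": variant,
                "n_replicates": n,
                "half_life_mean": float(grp["rna_half_life"].mean()),
                "half_life_sd": float(grp["rna_half_life"].std(ddof=1)) if n > 1 else 0.0,
                "k_trans_mean": float(grp["k_trans_hat"].mean()),
                "k_trans_sd": float(grp["k_trans_hat"].std(ddof=1)) if n > 1 else 0.0,
                "single_replicate": n == 1,
            }
        )
    return pd.DataFrame(rows)


def _prepare_groups(dataset: Sequence[TimeCourse]):
    """Group curves by identical time grid so exp(-b t), exp(-c t) are shared."""
    groups: dict[bytes, dict] = {}
    for tc in dataset:
        key = tc.times.tobytes()
        grp = groups.setdefault(key, {"times": tc.times, "curves": []})
        grp["curves"].append(tc)
    return list(groups.values())


def fit_global(
    dataset: Sequence[TimeCourse],
    config: FitConfig | None = None,
) -> HierarchicalFitResult:
    """Two-level fit of one cell line's time courses.

    The outer derivative-free search minimizes the sum over all curves of the
    inner (local) objective; per-variant local parameters are then computed
    at the global optimum and aggregated across technical replicates.
    """
    config = config or FitConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    cell_lines = sorted({tc.cell_line for tc in dataset})
    if len(cell_lines) > 1:
        raise ValueError(f"mixed cell lines in one fit: {cell_lines}")
    variants = sorted({tc.variant for tc in dataset})
    identifiable = len(variants) >= 2
    if not identifiable:
        warnings.warn(
            "single-variant dataset: shared maturation/decay rates are not "
            "identifiable from one variant; result flagged",
            UserWarning,
            stacklevel=2,
        )
    for tc in dataset:
        if not np.any(tc.signal > 0):
            raise FitError(
                f"all-zero signal for variant {tc.variant!r} replicate {tc.replicate}"
            )

    groups = _prepare_groups(dataset)
    starts_rna = tuple(LN2 / h for h in config.rna_start_half_lives)
    rate_lo = LN2 / config.protein_half_life_bounds[1]
    rate_hi = LN2 / config.protein_half_life_bounds[0]
    log_bounds = [(math.log(rate_lo), math.log(rate_hi))] * 2

    def total_objective(theta: np.ndarray, cfg: FitConfig) -> float:
        b = math.exp(min(max(theta[0], log_bounds[0][0]), log_bounds[0][1]))
        c = math.exp(min(max(theta[1], log_bounds[1][0]), log_bounds[1][1]))
        total = 0.0
        for grp in groups:
            t = grp["times"]
            eb = np.exp(-b * t)
            ec = np.exp(-c * t)
            for tc in grp["curves"]:
                fit = _fit_local_core(
                    t, tc.signal, b, c, starts_rna, cfg, eb=eb, ec=ec
                )
                total += fit.objective
        return total

    outer_starts = [
        np.array([math.log(LN2 / hb), math.log(LN2 / hc)])
        for hb, hc in itertools.product(
            config.k_mat_start_half_lives, config.lambda_fluor_start_half_lives
        )
    ]
    scale = total_objective(outer_starts[0], config)
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0

    # Stage 1: coarse Nelder-Mead from every start of the 3x3 grid (looser
    # inner tolerance); stage 2: one full-precision polish from the winner.
    coarse_cfg = replace(
        config, inner_log_tol=max(config.inner_log_tol, 5e-4)
    )
    best_theta, best_val = None, np.inf
    for theta0 in outer_starts:
        res = minimize(
            lambda th: total_objective(th, coarse_cfg) / scale,
            theta0,
            method="Nelder-Mead",
            bounds=log_bounds,
            options={
                "xatol": max(config.outer_xatol, 3e-2),
                "fatol": max(config.outer_fatol, 1e-6),
                "maxfev": 100,
            },
        )
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None:  # pragma: no cover - defensive
        raise FitError("outer search failed from every start")
    res = minimize(
        lambda th: total_objective(th, config) / scale,
        best_theta,
        method="Nelder-Mead",
        bounds=log_bounds,
        options={
            "xatol": config.outer_xatol,
            "fatol": config.outer_fatol,
            "maxfev": config.outer_maxfev,
        },
    )
    if res.fun < best_val:
        best_val, best_theta = res.fun, res.x

    b_hat = math.exp(min(max(best_theta[0], log_bounds[0][0]), log_bounds[0][1]))
    c_hat = math.exp(min(max(best_theta[1], log_bounds[1][0]), log_bounds[1][1]))
    # Exact swap symmetry of the two global rates: report the faster rate as
    # maturation (k_mat), the slower as fluorophore decay.
    k_mat_hat, lambda_fluor_hat = max(b_hat, c_hat), min(b_hat, c_hat)

    rows = []
    total_mae = 0.0
    for grp in groups:
        t = grp["times"]
        eb = np.exp(-k_mat_hat * t)
        ec = np.exp(-lambda_fluor_hat * t)
        for tc in grp["curves"]:
            fit = _fit_local_core(
                t, tc.signal, k_mat_hat, lambda_fluor_hat, starts_rna, config,
                eb=eb, ec=ec,
            )
            total_mae += fit.mae
            rows.append(
                {
                    "variant": tc.variant,
                    "replicate": tc.replicate,
                    "lambda_rna_hat": fit.lambda_rna,
                    "k_trans_hat": fit.k_trans,
                    "rna_half_life": half_life(fit.lambda_rna),
                    "mae": fit.mae,
                    "offset": fit.offset,
                }
            )
    per_variant = pd.DataFrame(rows).sort_values(
        ["variant", "replicate"], ignore_index=True
    )
    summary = aggregate_replicates(per_variant)
    return HierarchicalFitResult(
        cell_line=cell_lines[0],
        k_mat_hat=k_mat_hat,
        lambda_fluor_hat=lambda_fluor_hat,
        per_variant=per_variant,
        replicate_summary=summary,
        total_mae=total_mae,
        identifiable=identifiable,
        config=config,
    )
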