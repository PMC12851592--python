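"""Hard-core disk model of a pair-correlation curve and its fitting.

The model describes short-range liquid-like order of non-overlapping disks:

    g(r) = 0                                             for r < d
    g(r) = 1 + A · exp(−(r − d)/λ) · cos(2π (r − d)/P)   for r ≥ d

with minimum spacing d (μm), first-peak amplitude A (dimensionless), order
decay length λ (μm) and oscillation period P (μm). The exclusion
discontinuity at r = d makes joint gradient optimisation ill-posed, so d is
fitted on a grid (step = half the bin width) with (A, λ, P) solved by
nonlinear least squares at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .errors import InitializationError
from .rdf import RDFCurve

__all__ = ["HardCoreParams", "HardCoreFit", "model_rdf", "initialize_params", "fit_hardcore"]


@dataclass(frozen=True)
class HardCoreParams:
    d: float  # minimum spacing, μm
    A: float  # peak amplitude, dimensionless
    lam: float  # decay length λ, μm
    P: float  # oscillation period, μm

    def __post_init__(self):
        if self.d <= 0 or self.lam <= 0 or self.P <= 0:
            raise ValueError("d, λ and P must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")

    def to_dict(self) -> dict:
        return {"d_um": self.d, "A": self.A, "lambda_um": self.lam, "P_um": self.P}


@dataclass(frozen=True)
class HardCoreFit:
    params: HardCoreParams
    r_squared: float
    residuals: np.ndarray  # per-bin (empirical − model), same length as the curve
    converged: bool

    def to_dict(self) -> dict:
        out = self.params.to_dict()
        out.update({"r_squared": self.r_squared, "converged": self.converged})
        return out


def model_rdf(r_values, params: HardCoreParams) -> np.ndarray:
    """Evaluate the model g(r); zero below d, damped cosine about 1 above."""
    r = np.asarray(r_values, dtype=float)
    if (r < 0).any():
        raise ValueError("r values must be non-negative")
    g = np.zeros_like(r)
    mask = r >= params.d
    x = r[mask] - params.d
    g[mask] = 1.0 + params.A * np.exp(-x / params.lam) * np.cos(
        2.0 * np.pi * x / params.P
    )
    return g


def initialize_params(curve: RDFCurve) -> HardCoreParams:
    """Heuristic starting parameters read off the empirical curve.

    d₀: smallest r with g > 0.5 (the rise out of the exclusion zone);
    A₀: first-peak height above baseline; P₀: spacing of the first two local
    maxima, falling back to 2·d₀ when only one peak exists; λ₀ = P₀.
    """
    g = curve.g_values
    r = curve.r_centers
    if g.max() <= 1.0:
        raise InitializationError("curve has no peak above baseline (max g <= 1)")
    above = np.nonzero(g > 0.5)[0]
    if above.size == 0:
        raise InitializationError("curve never exceeds g = 0.5")
    d0 = float(r[above[0]])
    A0 = float(g.max() - 1.0)
    # require some prominence so per-bin noise wiggles do not masquerade as
    # oscillation peaks
    prominence = max(0.05, 0.1 * A0)
    maxima, _ = find_peaks(g, height=1.0, prominence=prominence)
    if maxima.size >= 2:
        P0 = float(r[maxima[1]] - r[maxima[0]])
    else:
        P0 = 2.0 * d0
    return HardCoreParams(d=d0, A=max(A0, 1e-6), lam=P0, P=P0)


def _fit_at_d(r, g, d, init, bounds, tol=1e-8, max_nfev=10_000):
    """Least squares for (A, λ, P) at fixed d over bins with r >= d."""
    mask = r >= d
    if mask.sum() < 3:
        return None
    r_fit, g_fit = r[mask], g[mask]

    def resid(x):
        A, lam, P = x
        t = r_fit - d
        return 1.0 + A * np.exp(-t / lam) * np.cos(2.0 * np.pi * t / P) - g_fit

    lo = [bounds["A"][0], bounds["lam"][0], bounds["P"][0]]
    hi = [bounds["A"][1], bounds["lam"][1], bounds["P"][1]]
    x0 = np.clip([init.A, init.lam, init.P], lo, hi)
    try:
        sol = least_squares(
            resid, x0, bounds=(lo, hi), ftol=tol, xtol=tol, gtol=tol, max_nfev=max_nfev
        )
    except Exception:
        return None
    return sol


def fit_hardcore(
    curve: RDFCurve,
    init: HardCoreParams | None = None,
    bounds: dict | None = None,
    d_grid_step: float | None = None,
) -> HardCoreFit:
    """Fit (d, A, λ, P) to an empirical pair-correlation curve.

    d runs over a grid (default step = bin_width / 2) inside its bounds; at
    each grid point (A, λ, P) are optimised by least squares over bins with
    r ≥ d. Grid points are ranked by total squared error over *all* bins —
    bins below the candidate d count (g_emp − 0)² — so pushing d outward
    cannot shrink the cost by discarding the peak; ties in cost resolve to
    the smallest d. Non-convergence is reported via ``converged=False``,
    never raised.
    """
    if init is None:
        init = initialize_params(curve)  # propagates InitializationError
    r, g = curve.r_centers, curve.g_values
    r_max = float(curve.r_max)
    bw = float(curve.bin_width)
    default_bounds = {
        "d": (bw / 2.0, r_max / 2.0),
        "A": (0.0, 10.0),
        "lam": (1e-6, r_max),
        "P": (bw, r_max),
    }
    if bounds:
        default_bounds.update(bounds)
    b = default_bounds
    step = d_grid_step if d_grid_step is not None else bw / 2.0
    d_grid = np.arange(b["d"][0], b["d"][1] + step / 2.0, step)
    # always include the initial estimate of d in the grid
    if not np.any(np.isclose(d_grid, init.d, atol=step / 4.0)):
        d_grid = np.sort(np.append(d_grid, np.clip(init.d, *b["d"])))

    # multistart in the oscillation period: the cost is multimodal in P and a
    # single start can lock onto a harmonic or chase bin noise
    starts = [
        HardCoreParams(init.d, init.A, init.lam, p0)
        for p0 in (init.P, 0.5 * init.P, 2.0 * init.P)
        if b["P"][0] < p0 <= b["P"][1]
    ] or [init]

    best = None  # (cost, d, sol)
    for d in d_grid:
        for start in starts:
            sol = _fit_at_d(r, g, d, start, b)
            if sol is None:
                continue
            A, lam, P = (float(v) for v in sol.x)
            full_model = model_rdf(r, HardCoreParams(float(d), A, lam, P))
            cost = float(np.sum((g - full_model) ** 2))
            if best is None or cost < best[0] - 1e-12:
                best = (cost, float(d), sol)

    if best is None:
        flat = HardCoreParams(init.d, init.A, init.lam, init.P)
        return HardCoreFit(flat, -np.inf, g - model_rdf(r, flat), converged=False)

    cost, d_hat, sol = best
    A, lam, P = sol.x
    params = HardCoreParams(d_hat, float(max(A, 0.0)), float(lam), float(P))
    model_vals = model_rdf(r, params)
    residuals = g - model_vals
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else np.nan
    return HardCoreFit(params, r2, residuals, converged=bool(sol.success))
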