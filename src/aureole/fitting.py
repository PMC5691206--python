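"""Model fits: spreading velocity, velocity enhancement, and uptake saturation.

The three regressions mirror how the experimental quantities are extracted:

* ``fit_velocity`` — ordinary least squares of the spread area on time;
  the slope divided by the aggregate radius is the spreading velocity V*
  and the slope itself is the diffusion coefficient D = V* R0.
* ``fit_enhancement`` — the piecewise law V*(phi_S) = V0 (1 + alpha phi_S)
  clamped at a plateau coverage, fitted by a coarse grid over the breakpoint
  with a linear least-squares solve per candidate (robust with the handful
  of coverage levels actually measured).
* ``fit_uptake`` — the two-branch saturation of Delta/R versus phi_S:
  below a threshold coverage all particles are internalized and Delta/R is
  linear in phi_S (slope -> phi_is); above it the membrane adsorbs the
  excess, phi_s = a (phi_S - phi_S0), producing a plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import CellGeometry, ParticleSpec, particle_counts
from .presets import Preset
from .synth import SpreadingRecord

__all__ = [
    "FitResult",
    "fit_velocity",
    "fit_enhancement",
    "fit_uptake",
    "phi_is_from_Rc",
    "build_table1",
]


@dataclass
class FitResult:
    """Point estimates with standard errors plus fit diagnostics."""

    params: dict
    se: dict = field(default_factory=dict)
    rss: float = math.nan
    n: int = 0
    flags: list = field(default_factory=list)
    branch: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


# ---------------------------------------------------------------------------
# Spreading velocity
# ---------------------------------------------------------------------------

def fit_velocity(rec: SpreadingRecord) -> FitResult:
    """OLS fit of A(t): V* = slope / R0 [um/s], D = slope [um^2/s]."""
    t, A = np.asarray(rec.t_s, float), np.asarray(rec.A_um2, float)
    if t.size < 3:
        raise ValueError("need at least 3 time points to fit a velocity")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite areas in trajectory")
    res = stats.linregress(t, A)
    V_star = res.slope / rec.R0_um
    flags = []
    if res.slope < 0:
        flags.append("non-spreading: fitted area slope is negative")
    pred = res.intercept + res.slope * t
    return FitResult(
        params={"V_star_um_s": V_star, "D_um2_s": res.slope, "A0_um2": res.intercept},
        se={"V_star_um_s": res.stderr / rec.R0_um, "D_um2_s": res.stderr},
        rss=float(np.sum((A - pred) ** 2)),
        n=int(t.size),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Velocity enhancement
# ---------------------------------------------------------------------------

def _piecewise_ls(x: np.ndarray, y: np.ndarray, bp: float, w: np.ndarray):
    """Least squares of y = b0 + b1 * min(x, bp); returns (beta, cov, rss)."""
    X = np.column_stack([np.ones_like(x), np.minimum(x, bp)])
    Xw = X * w[:, None]
    yw = y * w
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ beta
    rss = float(np.sum((w * resid) ** 2))
    dof = max(x.size - 2, 1)
    try:
        cov = np.linalg.inv(Xw.T @ Xw) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return beta, cov, rss


def fit_enhancement(
    points, weights=None, grid_step: float = 0.05, refine_step: float = 0.01
) -> FitResult:
    """Fit V*(phi_S) = V0 (1 + alpha phi_S) clamped at phi_S_plateau.

    ``points`` is a sequence of (phi_S, V*) pairs.  Writing
    V = b0 + b1 min(phi_S, plateau) with b0 = V0 and b1 = V0 alpha makes the
    model linear for a fixed breakpoint, so the breakpoint is found by a
    coarse grid (step 0.05) refined locally (step 0.01).  Optional weights
    1/SD (per-point) enable weighted least squares.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (phi_S, V*) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if x.size < 4:
        raise ValueError("need at least 4 (phi_S, V*) points")
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)

    flags = []
    lo, hi = x.min(), x.max()

    def admissible(bp):
        # the linear branch needs enough leverage to pin slope + intercept
        return np.sum(x < bp) >= 3 and np.sum(x >= bp) >= 1

    grid = np.round(np.arange(lo + grid_step, hi + grid_step / 2, grid_step), 10)
    results = {bp: _piecewise_ls(x, y, bp, w) for bp in grid if admissible(bp)}
    if not results:
        # all points on one branch: pure linear fit, plateau unidentifiable
        results = {float(hi): _piecewise_ls(x, y, hi, w)}
        flags.append("phi_S_plateau unidentifiable: all points on the linear branch")
    bp_best = min(results, key=lambda bp: results[bp][2])
    fine = np.round(np.arange(bp_best - grid_step, bp_best + grid_step, refine_step), 10)
    for bp in fine:
        if lo < bp <= hi and bp not in results and admissible(bp):
            results[bp] = _piecewise_ls(x, y, bp, w)
    bp_best = min(results, key=lambda bp: results[bp][2])
    beta, cov, rss = results[bp_best]

    V0, b1 = float(beta[0]), float(beta[1])
    alpha = b1 / V0 if V0 != 0 else math.nan
    # delta-method SE for alpha = b1/b0
    if np.all(np.isfinite(cov)) and V0 != 0:
        var_a = (
            cov[1, 1] / V0**2
            + b1**2 * cov[0, 0] / V0**4
            - 2 * b1 * cov[0, 1] / V0**3
        )
        se_alpha = math.sqrt(max(var_a, 0.0))
    else:
        se_alpha = math.nan

    rss_values = [r[2] for r in results.values()]
    n_above = int(np.sum(x > bp_best))
    if n_above == 0 or bp_best >= hi:
        if not flags:
            flags.append("phi_S_plateau unidentifiable: no points beyond the breakpoint")
    # flat response: the breakpoint location does not change the fit at all
    y_scale = float(np.sum((w * y) ** 2)) + 1e-300
    if len(rss_values) > 1 and (max(rss_values) - min(rss_values)) <= 1e-9 * y_scale:
        flags.append("phi_S_plateau unidentifiable: flat response")

    return FitResult(
        params={"V0_um_s": V0, "alpha": alpha, "phi_S_plateau": float(bp_best)},
        se={
            "V0_um_s": float(math.sqrt(max(cov[0, 0], 0.0))) if np.isfinite(cov[0, 0]) else math.nan,
            "alpha": se_alpha,
        },
        rss=rss,
        n=int(x.size),
        flags=flags,
        branch={"n_linear": int(np.sum(x <= bp_best)), "n_plateau": n_above},
    )


# ---------------------------------------------------------------------------
# Uptake saturation
# ---------------------------------------------------------------------------

def _uptake_rss(x, y, phi_S0, K):
    """Given threshold and K = 3 phi_is V_cell/(d A_cell), fit a; return rss."""
    below = x <= phi_S0
    pred = np.empty_like(y)
    pred[below] = x[below] / K
    xa, ya = x[~below], y[~below]
    if xa.size:
        # K + 4 a (x - phi_S0) = x / y  is linear in a
        z = xa / ya - K
        u = 4.0 * (xa - phi_S0)
        denom = float(np.sum(u * u))
        a = float(np.sum(z * u) / denom) if denom > 0 else 0.0
        a = max(a, 0.0)
        pred[~below] = xa / (K + 4.0 * a * (xa - phi_S0))
    else:
        a = math.nan
    return float(np.sum((y - pred) ** 2)), a, pred


def fit_uptake(
    points,
    g: CellGeometry,
    p: ParticleSpec,
    grid_step: float = 0.05,
    refine_step: float = 0.01,
    joint: bool = False,
) -> FitResult:
    """Two-branch fit of Delta/R versus phi_S: recovers (phi_is, a, phi_S0).

    Branch 1 (phi_S <= phi_S0, all particles internalized): Delta/R is
    linear through the origin with slope d A_cell / (3 phi_is V_cell), so
    the through-origin slope of the low-coverage points yields phi_is.
    Branch 2: substituting phi_s = a (phi_S - phi_S0) into the conservation
    law gives Delta/R = phi_S / (K + 4 a (phi_S - phi_S0)), linear in ``a``
    once the threshold is fixed.  The threshold is grid-searched (coarse
    then refined), with phi_is fixed from branch 1 before fitting ``a``
    (two-step, as the quantities are reported); ``joint=True`` refits
    phi_is together with ``a`` at the best threshold.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (phi_S, Delta/R) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.all(y == 0):
        raise ValueError("Delta/R is identically zero: nothing to fit")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("phi_S and Delta/R must be >= 0")

    geom = g.V_cell_um3 / (p.d_um * g.A_cell_um2)

    def eval_threshold(phi_S0):
        below = (x <= phi_S0) & (y > 0)
        if below.sum() < 3 or (~(x <= phi_S0)).sum() < 2:
            return None
        xb, yb = x[below], y[below]
        slope = float(np.sum(xb * yb) / np.sum(xb * xb))  # through-origin OLS
        # Delta/R = phi_S d A_cell / (3 phi_is V_cell)  =>  phi_is = 1/(3 geom slope)
        phi_is = 1.0 / (3.0 * geom * slope)
        K = 3.0 * phi_is * geom
        rss, a, pred = _uptake_rss(x, y, phi_S0, K)
        return rss, phi_is, a, pred

    lo, hi = x.min(), x.max()
    candidates = np.round(np.arange(lo, hi, grid_step), 10)
    evaluated = {c: eval_threshold(c) for c in candidates}
    evaluated = {c: r for c, r in evaluated.items() if r is not None}
    if not evaluated:
        raise ValueError(
            "no admissible threshold: need >= 3 points below and >= 2 above phi_S0"
        )
    best = min(evaluated, key=lambda c: evaluated[c][0])
    fine = np.round(np.arange(best - grid_step, best + grid_step, refine_step), 10)
    for c in fine:
        if c not in evaluated:
            r = eval_threshold(c)
            if r is not None:
                evaluated[c] = r
    best = min(evaluated, key=lambda c: evaluated[c][0])
    rss, phi_is, a, pred = evaluated[best]

    if joint:
        from scipy.optimize import least_squares

        def resid(theta):
            pi, aa = theta
            K = 3.0 * pi * geom
            below = x <= best
            out = np.empty_like(y)
            out[below] = x[below] / K
            out[~below] = x[~below] / (K + 4.0 * aa * (x[~below] - best))
            return out - y

        sol = least_squares(resid, x0=[phi_is, max(a, 0.0)], bounds=([1e-6, 0], [1, 10]))
        phi_is, a = map(float, sol.x)
        rss = float(np.sum(sol.fun**2))
        pred = y + sol.fun

    dof = max(x.size - 3, 1)
    sigma2 = rss / dof
    below = (x <= best) & (y > 0)
    # through-origin slope variance -> phi_is by the delta method
    var_slope = sigma2 / float(np.sum(x[below] ** 2)) if below.any() else math.nan
    slope = 1.0 / (3.0 * geom * phi_is)
    se_phi_is = math.sqrt(var_slope) * phi_is / slope if np.isfinite(var_slope) else math.nan

    return FitResult(
        params={"phi_is": float(phi_is), "a": float(a), "phi_S0": float(best)},
        se={"phi_is": se_phi_is},
        rss=rss,
        n=int(x.size),
        branch={"n_below": int(below.sum()), "n_above": int(np.sum(x > best))},
    )


def phi_is_from_Rc(
    Rc_um: float, phi_S: float, g: CellGeometry, p: ParticleSpec
) -> float:
    """Saturation volume fraction from a single (R_c, phi_S) measurement.

    Inverts R_c phi_S = 3 phi_is (d_cell/d)(V_cell/A_cell):
    a quick estimate of phi_is from where the aureole starts to widen.
    """
    if Rc_um <= 0 or phi_S <= 0:
        raise ValueError("R_c and phi_S must be > 0")
    return Rc_um * phi_S * p.d_um * g.A_cell_um2 / (3.0 * g.d_cell_um * g.V_cell_um3)


# ---------------------------------------------------------------------------
# Per-condition summary table
# ---------------------------------------------------------------------------

def build_table1(presets: list[Preset]) -> pd.DataFrame:
    """Per-cell particle loads for every coverage level of every preset.

    Rows: (particle, phi_S, phi_is, phi_s, phi_S0, n_i, n_s, n_tot), with
    counts from the conservation model; below the adsorption threshold
    n_s = 0 exactly.
    """
    rows = []
    for preset in presets:
        if preset.particle is None or preset.phi_is <= 0:
            continue
        for phi_S in preset.phi_S_levels:
            up = preset.uptake(phi_S)
            n_i, n_s, n_tot = particle_counts(up, preset.geometry, preset.particle)
            rows.append(
                {
                    "particle": preset.name,
                    "phi_S": phi_S,
                    "phi_is": up.phi_is,
                    "phi_s": up.phi_s,
                    "phi_S0": preset.phi_S0,
                    "n_i": n_i,
                    "n_s": n_s,
                    "n_tot": n_tot,
                }
            )
    return pd.DataFrame(rows)
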