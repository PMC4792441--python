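"""Pixel-wise three-parameter inversion-recovery fitting and delta maps.

The signal model is the magnitude inversion-recovery curve

    S(TI) = | S0 * (1 - B * exp(-R1 * TI)) |

with S0 the signal at full relaxation, B the dimensionless inversion
efficiency (2 for a perfect inversion) and R1 the longitudinal relaxation
rate. The folded curve is fitted directly — no polarity-restoration
heuristic is applied to the data — by bounded nonlinear least squares,
started from a polarity-aware variable-projection scan over R1 plus
deterministic restarts. Every pixel is fitted independently.

Derived maps: dR1 = R1_O2 - R1_air (oxygen uptake, s^-1) and
dR2* = ln(S0_air / S0_O2) / TE (alveolar oxygen delivery, ms^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .protocol import AcquisitionProtocol, ImageSeries, ParameterMaps

__all__ = [
    "FitConfig",
    "PixelFit",
    "fit_ir_pixel",
    "fit_maps",
    "delta_r1",
    "delta_r2star",
]


@dataclass(frozen=True)
class FitConfig:
    """Bounds and optimizer settings for the per-pixel IR fit.

    R1 bounds in s^-1; ``n_multistart`` counts optimizer starts (the
    scan-based start plus deterministic R1-scaled restarts); a fit whose
    RMS residual exceeds ``max_rel_residual`` times the fitted S0 is
    flagged invalid, as is any fit that stops on a finite bound.
    """

    r1_bounds: tuple[float, float] = (0.01, 20.0)
    inv_eff_bounds: tuple[float, float] = (0.0, 2.1)
    s0_bounds: tuple[float, float] = (1e-12, np.inf)
    max_iterations: int = 1000
    tolerance: float = 1e-10
    n_multistart: int = 2
    max_rel_residual: float = 0.5
    r1_scan_points: int = 24

    def __post_init__(self) -> None:
        for name in ("r1_bounds", "inv_eff_bounds", "s0_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a nonempty interval, got ({lo}, {hi})")
        if self.n_multistart < 1:
            raise ValueError("n_multistart must be >= 1")


class PixelFit(NamedTuple):
    s0: float
    inv_eff: float
    r1: float          # s^-1
    residual: float    # sum of squared residuals
    fit_ok: bool


class _ScanDesign:
    """Precomputed exponentials for the coarse variable-projection scan.

    For each trial R1 the model is linear in (a, b) = (S0, -S0*B):
    S = a + b*exp(-R1 t). Both polarity hypotheses of the magnitude data
    (no fold, or fold before the signal minimum) are screened.
    """

    def __init__(self, t_s: np.ndarray, config: FitConfig):
        lo = max(config.r1_bounds[0], 1e-3)
        hi = min(config.r1_bounds[1], 1e3)
        self.r1_grid = np.geomspace(lo, hi, config.r1_scan_points)
        self.t_s = t_s
        self.E = np.exp(-np.outer(self.r1_grid, t_s))  # (n_r1, n_t)
        n = t_s.size
        self.n = n
        self.Sx = self.E.sum(axis=1)
        self.Sxx = (self.E * self.E).sum(axis=1)
        self.denom = n * self.Sxx - self.Sx**2

    def best_start(self, y: np.ndarray) -> tuple[float, float, float]:
        """Return (s0, B, r1) of the best linearized fit over the scan."""
        k0 = int(np.argmin(y))
        best = None
        for k in sorted({k0, k0 + 1} & set(range(self.n + 1))):
            ys = y.copy()
            ys[:k] *= -1.0
            Sy = ys.sum()
            Sxy = self.E @ ys
            with np.errstate(divide="ignore", invalid="ignore"):
                b = (self.n * Sxy - self.Sx * Sy) / self.denom
            b = np.where(np.isfinite(b), b, 0.0)
            a = (Sy - b * self.Sx) / self.n
            resid = a[:, None] + b[:, None] * self.E - ys[None, :]
            ssr = np.einsum("ij,ij->i", resid, resid)
            i = int(np.argmin(ssr))
            if best is None or ssr[i] < best[0]:
                best = (ssr[i], a[i], b[i], self.r1_grid[i])
        _, a, b, r1 = best
        s0 = a if a > 0 else max(np.max(np.abs(y)), 1e-6)
        inv_eff = -b / s0 if s0 > 0 else 2.0
        return float(s0), float(inv_eff), float(r1)


def _residual_and_jac(t_s: np.ndarray, y: np.ndarray):
    def fun(p):
        s0, b, r1 = p
        f = s0 * (1.0 - b * np.exp(-r1 * t_s))
        return np.abs(f) - y

    def jac(p):
        s0, b, r1 = p
        e = np.exp(-r1 * t_s)
        f = s0 * (1.0 - b * e)
        sgn = np.where(f >= 0, 1.0, -1.0)
        return np.column_stack((sgn * (1.0 - b * e), sgn * (-s0 * e), sgn * (s0 * b * t_s * e)))

    return fun, jac


def _clip_interior(x: float, lo: float, hi: float) -> float:
    eps = 1e-9 * (1.0 + abs(x))
    lo2 = lo + eps if np.isfinite(lo) else lo
    hi2 = hi - eps if np.isfinite(hi) else hi
    return float(min(max(x, lo2), hi2))


def _near_bound(x: float, lo: float, hi: float) -> bool:
    tol = 1e-6 * (1.0 + abs(x))
    return (np.isfinite(lo) and abs(x - lo) < tol) or (np.isfinite(hi) and abs(x - hi) < tol)


#: Deterministic R1 scale factors for multistart restarts.
_RESTART_LADDER = (1.0, 0.25, 4.0, 0.0625, 16.0, 0.015625, 64.0)


def fit_ir_pixel(
    signal: np.ndarray,
    protocol: AcquisitionProtocol,
    config: FitConfig = FitConfig(),
    ti_unit: str = "ms",
    _scan: _ScanDesign | None = None,
) -> PixelFit:
    """Fit one pixel's magnitude IR curve; R1 returned in s^-1.

    Raises ``ValueError`` on NaN/negative signal entries or a length
    mismatch with the protocol. Degenerate signals (all zero) return
    ``fit_ok=False`` rather than raising.
    """
    y = np.asarray(signal, dtype=float)
    if y.shape != (protocol.n_inversion_times,):
        raise ValueError(
            f"signal length {y.shape} does not match {protocol.n_inversion_times} inversion times"
        )
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("signal must be finite and nonnegative")
    if ti_unit == "ms":
        t_s = np.asarray(protocol.inversion_times, dtype=float) / 1000.0
    elif ti_unit == "s":
        t_s = np.asarray(protocol.inversion_times, dtype=float)
    else:
        raise ValueError(f"ti_unit must be 'ms' or 's', got {ti_unit!r}")

    if np.max(y) <= 0:
        return PixelFit(np.nan, np.nan, np.nan, np.nan, False)

    scan = _scan if _scan is not None else _ScanDesign(t_s, config)
    s0_i, b_i, r1_i = scan.best_start(y)
    lo = np.array([config.s0_bounds[0], config.inv_eff_bounds[0], config.r1_bounds[0]])
    hi = np.array([config.s0_bounds[1], config.inv_eff_bounds[1], config.r1_bounds[1]])
    fun, jac = _residual_and_jac(t_s, y)

    best = None
    early_stop = (1e-9 * max(np.max(y), 1.0)) ** 2 * y.size
    for factor in _RESTART_LADDER[: config.n_multistart]:
        x0 = np.array(
            [
                _clip_interior(s0_i, lo[0], hi[0]),
                _clip_interior(b_i if factor == 1.0 else 2.0, lo[1], hi[1]),
                _clip_interior(r1_i * factor, lo[2], hi[2]),
            ]
        )
        try:
            res = least_squares(
                fun,
                x0,
                jac=jac,
                bounds=(lo, hi),
                method="trf",
                xtol=config.tolerance,
                ftol=config.tolerance,
                gtol=config.tolerance,
                max_nfev=config.max_iterations,
            )
        except Exception:
            continue
        ssr = float(2.0 * res.cost)
        if best is None or ssr < best[0] - 1e-14 * (1 + best[0]) or (
            abs(ssr - best[0]) <= 1e-12 * (1 + best[0]) and res.x[2] < best[1].x[2]
        ):
            best = (ssr, res)
        if best[0] < early_stop:
            break

    if best is None:
        return PixelFit(np.nan, np.nan, np.nan, np.nan, False)
    ssr, res = best
    s0, b, r1 = (float(v) for v in res.x)
    rms = np.sqrt(ssr / y.size)
    ok = bool(
        res.success
        and not _near_bound(s0, *config.s0_bounds)
        and not _near_bound(b, *config.inv_eff_bounds)
        and not _near_bound(r1, *config.r1_bounds)
        and rms <= config.max_rel_residual * max(s0, 1e-12)
    )
    return PixelFit(s0, b, r1, ssr, ok)


def fit_maps(series: ImageSeries, config: FitConfig = FitConfig()) -> ParameterMaps:
    """Fit every in-mask pixel independently for each gas state.

    Out-of-mask pixels carry NaN in all maps and ``fit_ok=False``.
    Per-pixel failures set ``fit_ok=False`` without aborting; the delta
    maps are populated only where both gas-state fits succeeded.
    """
    protocol = series.protocol
    t_s = np.asarray(protocol.inversion_times, dtype=float) / 1000.0
    scan = _ScanDesign(t_s, config)
    shape = series.shape
    nan_map = lambda: np.full(shape, np.nan)

    s0, r1, inv_eff, residual, fit_ok = {}, {}, {}, {}, {}
    rows, cols = np.nonzero(series.mask)
    for state in protocol.gas_states:
        s0[state] = nan_map()
        r1[state] = nan_map()
        inv_eff[state] = nan_map()
        residual[state] = nan_map()
        fit_ok[state] = np.zeros(shape, dtype=bool)
        stack = series.images[state]
        for i, j in zip(rows, cols):
            px = fit_ir_pixel(stack[:, i, j], protocol, config, _scan=scan)
            s0[state][i, j] = px.s0
            r1[state][i, j] = px.r1
            inv_eff[state][i, j] = px.inv_eff
            residual[state][i, j] = px.residual
            fit_ok[state][i, j] = px.fit_ok

    air, o2 = protocol.gas_states
    both = fit_ok[air] & fit_ok[o2]
    dr1 = np.where(both, delta_r1(r1[o2], r1[air]), np.nan)
    dr2s = np.where(both, delta_r2star(s0[air], s0[o2], protocol.echo_time), np.nan)
    return ParameterMaps(
        s0=s0,
        r1=r1,
        inv_eff=inv_eff,
        residual=residual,
        fit_ok=fit_ok,
        delta_r1=dr1,
        delta_r2star=dr2s,
        mask=series.mask,
        group=series.group,
        animal_id=series.animal_id,
    )


def delta_r1(r1_o2_map: np.ndarray, r1_air_map: np.ndarray) -> np.ndarray:
    """Oxygen-uptake map dR1 = R1_O2 - R1_air, in s^-1 (NaN propagates)."""
    a = np.asarray(r1_o2_map, dtype=float)
    b = np.asarray(r1_air_map, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a - b


def delta_r2star(
    s0_air_map: np.ndarray, s0_o2_map: np.ndarray, echo_time: float
) -> np.ndarray:
    """Oxygen-delivery map dR2* = ln(S0_air / S0_O2) / TE, in ms^-1.

    ``echo_time`` in ms. Negative outputs (S0_O2 > S0_air) are returned
    as-is; pixels where either S0 is nonpositive or non-finite become NaN.
    """
    if not echo_time > 0:
        raise ValueError(f"echo_time must be positive, got {echo_time}")
    a = np.asarray(s0_air_map, dtype=float)
    b = np.asarray(s0_o2_map, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(a / b) / echo_time
    bad = ~(np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0))
    if out.ndim == 0:
        return np.float64(np.nan) if bad else out
    out[bad] = np.nan
    return out
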