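"""Scaling analysis of the anchoring entropy.

The anchoring cost D(N) = -ΔS/k_B of a chain grafted to a rough surface is
summarized by two asymptotic laws:

* a power law ``D = A * N**ζ`` (log-log linear), whose exponent ζ tends to a
  plateau value ζ* on sufficiently rough self-similar surfaces and to 1 in
  the extreme-roughness limit;
* for a smooth planar wall, the universal-exponent form
  ``ΔS/k_B = Δγ ln N`` with Δγ = γ^A - γ^F (γ^F = 7/6 for the free chain).

The renormalization-group entropy of a free chain,
``S/k_B = ln C + (γ-1) ln N + N ln ω_eff``, is linear in
``(ln C, γ-1, ln ω_eff)`` and is fitted by exact linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .lattice import bond_length

#: Universal entropic exponent of a free self-avoiding chain in 3-D.
GAMMA_FREE = 7.0 / 6.0

#: Flory exponent of the athermal (good-solvent) coil.
NU_FLORY = 3.0 / 5.0


@dataclass
class ScalingFit:
    """Result of a power-law or log-slope fit of the anchoring entropy."""

    model: Literal["power_law", "log_slope"]
    zeta: Optional[float] = None
    A: Optional[float] = None
    delta_gamma: Optional[float] = None
    intercept: Optional[float] = None
    fit_range: tuple[float, float] = (0.0, 0.0)
    r_squared: float = 0.0
    residuals: Optional[np.ndarray] = None


@dataclass
class PlateauResult:
    """Plateau exponent ζ* and the roughness threshold where it is reached."""

    zeta_star: float
    DF_crit: float
    tolerance: float


def _select_range(
    n_values: np.ndarray, y: np.ndarray, fit_range: tuple[float, float] | None
):
    if fit_range is not None:
        lo, hi = fit_range
        mask = (n_values >= lo) & (n_values <= hi)
    else:
        mask = np.ones(n_values.shape, dtype=bool)
    return n_values[mask], y[mask]


def _wls_line(x, y, weights=None):
    """Weighted least-squares line fit; returns slope, intercept, r², resid."""
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
    pred = np.polyval(coeffs, x)
    resid = y - pred
    ss_res = float((w * resid**2).sum())
    ybar = float((w * y).sum() / w.sum())
    ss_tot = float((w * (y - ybar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coeffs[0]), float(coeffs[1]), r2, resid


def fit_power_law(
    n_values: Sequence[float],
    anchoring_cost: Sequence[float],
    fit_range: tuple[float, float] | None = None,
    weights: Sequence[float] | None = None,
) -> ScalingFit:
    """Fit ``-ΔS/k_B = A * N**ζ`` by least squares on the log-log line.

    ``anchoring_cost`` holds the positive costs D(N) = -ΔS/k_B; values must
    be strictly positive inside the fit range.
    """
    n_arr = np.asarray(n_values, dtype=float)
    d_arr = np.asarray(anchoring_cost, dtype=float)
    n_arr, d_arr = _select_range(n_arr, d_arr, fit_range)
    if len(n_arr) < 2:
        raise ValueError("need at least two points in the fit range")
    if np.any(d_arr <= 0):
        raise ValueError(
            "anchoring cost must be positive throughout the fit range"
        )
    if weights is not None:
        weights = np.asarray(weights, float)[
            np.isin(np.asarray(n_values, float), n_arr)
        ]
    slope, intercept, r2, resid = _wls_line(
        np.log(n_arr), np.log(d_arr), weights
    )
    return ScalingFit(
        model="power_law",
        zeta=slope,
        A=float(np.exp(intercept)),
        intercept=intercept,
        fit_range=(float(n_arr.min()), float(n_arr.max())),
        r_squared=r2,
        residuals=resid,
    )


def fit_log_slope(
    n_values: Sequence[float],
    delta_s: Sequence[float],
    fit_range: tuple[float, float] | None = None,
    weights: Sequence[float] | None = None,
) -> ScalingFit:
    """Fit ``ΔS/k_B = Δγ ln N + const`` (planar-wall universal form).

    The intercept is left free and reported; the slope estimates
    Δγ = γ^A - γ^F.
    """
    n_arr = np.asarray(n_values, dtype=float)
    s_arr = np.asarray(delta_s, dtype=float)
    n_arr, s_arr = _select_range(n_arr, s_arr, fit_range)
    if len(n_arr) < 4:
        raise ValueError("need at least four points for the log-slope fit")
    if n_arr.max() == n_arr.min():
        raise ValueError("degenerate N range")
    if weights is not None:
        weights = np.asarray(weights, float)[
            np.isin(np.asarray(n_values, float), n_arr)
        ]
    slope, intercept, r2, resid = _wls_line(np.log(n_arr), s_arr, weights)
    return ScalingFit(
        model="log_slope",
        delta_gamma=slope,
        intercept=intercept,
        fit_range=(float(n_arr.min()), float(n_arr.max())),
        r_squared=r2,
        residuals=resid,
    )


def rg_entropy(
    n_segments: float, C: float, gamma: float, omega_eff: float
) -> float:
    """Renormalization-group free-chain entropy
    ``S/k_B = ln C + (γ-1) ln N + N ln ω_eff``."""
    if C <= 0 or omega_eff <= 0:
        raise ValueError("C and omega_eff must be positive")
    return float(
        np.log(C) + (gamma - 1.0) * np.log(n_segments) + n_segments * np.log(omega_eff)
    )


def fit_rg_entropy(
    n_values: Sequence[float],
    entropies: Sequence[float],
    gamma: float | None = None,
) -> tuple[float, float, float, float]:
    """Fit ``(C, γ, ω_eff)`` of the RG entropy form to simulated S(N).

    The model is linear in ``(ln C, γ-1, ln ω_eff)`` so the fit is exact
    linear least squares.  Pass ``gamma`` to hold the universal exponent
    fixed (e.g. 7/6 for free chains).  Returns ``(C, gamma, omega_eff, r²)``.
    """
    n_arr = np.asarray(n_values, dtype=float)
    s_arr = np.asarray(entropies, dtype=float)
    if gamma is None:
        design = np.column_stack([np.ones_like(n_arr), np.log(n_arr), n_arr])
        beta, *_ = np.linalg.lstsq(design, s_arr, rcond=None)
        c0, g1, w = beta
        gamma_hat = g1 + 1.0
    else:
        target = s_arr - (gamma - 1.0) * np.log(n_arr)
        design = np.column_stack([np.ones_like(n_arr), n_arr])
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        c0, w = beta
        gamma_hat = gamma
    pred = c0 + (gamma_hat - 1.0) * np.log(n_arr) + w * n_arr
    ss_res = float(((s_arr - pred) ** 2).sum())
    ss_tot = float(((s_arr - s_arr.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(c0)), float(gamma_hat), float(np.exp(w)), r2


def detect_plateau(
    df_values: Sequence[float],
    zeta_values: Sequence[float],
    tol: float = 0.02,
) -> PlateauResult:
    """Find the trailing plateau of the ζ(D_F) curve.

    The plateau is the maximal trailing run in which consecutive ζ values
    differ by less than ``tol``; ζ* is the mean over the run and D_F^crit
    the smallest D_F in it.  Raises if no run of length >= 2 exists.
    """
    df_arr = np.asarray(df_values, dtype=float)
    z_arr = np.asarray(zeta_values, dtype=float)
    if len(df_arr) < 5:
        raise ValueError("need at least five (D_F, ζ) points")
    if np.any(np.diff(df_arr) <= 0):
        raise ValueError("D_F values must be strictly ascending")
    start = len(z_arr) - 1
    while start > 0 and abs(z_arr[start] - z_arr[start - 1]) < tol:
        start -= 1
    if start > len(z_arr) - 2:
        raise ValueError(f"no plateau of length >= 2 within tol={tol}")
    run = z_arr[start:]
    return PlateauResult(
        zeta_star=float(run.mean()),
        DF_crit=float(df_arr[start]),
        tolerance=tol,
    )


def flory_size(
    n_segments: int,
    b_over_a: float | None = None,
    nu: float = NU_FLORY,
) -> float:
    """Flory coil size ``R_H/a = (b/a) N**ν`` (ν = 3/5 in athermal solvent)."""
    if n_segments < 1:
        raise ValueError(f"need N >= 1, got {n_segments}")
    if b_over_a is None:
        b_over_a = bond_length(1.0)
    return float(b_over_a * n_segments**nu)
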