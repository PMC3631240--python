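"""Closed-form model of tumour-kill by a diffusing cytotoxin.

A scarce cytotoxic T cell secretes a small molecule (IFN-γ in the motivating
system) that diffuses into the surrounding tissue and is taken up by tumour
cells.  At quasi-steady state the interstitial concentration ``σ(r)`` around a
single spherical source of radius ``R_T`` obeys

    D ∇²σ = λ σ,

whose decaying, spherically symmetric solution with ``σ(R_T) = σ_T`` is

    σ(r)/σ_T = (R_T / r) · exp(−(r − R_T)/L),        L = sqrt(D/λ).

``L`` is the diffusion penetration distance: the length scale over which
uptake depletes the cytotoxin.

Each T cell "serves" the ``1/ρ`` tumour cells sharing its interaction sphere,
where ``ρ`` is the T-cell : tumour-cell number ratio.  The interaction radius
``R`` satisfies a volume balance ``R³ = R_T³ + R_C³/ρ`` with tumour-cell
radius ``R_C``.  The predicted kill fraction is the maximal kill ``f_max``
scaled by the volume average of ``σ/σ_T`` over that sphere; the radial
integral is elementary, so the model is fully closed-form.

Three normalisation conventions are provided for the volume average, because
the exposure of the volume occupied by the T cell itself can be counted in
more than one way (see :data:`CONVENTIONS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDesignError, DomainError, InsufficientDataError

__all__ = [
    "CONVENTIONS",
    "KillModelParams",
    "ConcentrationField",
    "DoseResponsePoint",
    "FitResult",
    "PenetrationReference",
    "concentration_ratio",
    "interaction_radius",
    "kill_fraction",
    "predict_curve",
    "fit_kill_model",
    "fit_two_point_exact",
    "penetration_from_reference",
]

#: Normalisation conventions for the volume-averaged exposure.
#:
#: ``"shell"`` (default)
#:     Average σ/σ_T over the tumour-occupied shell ``R_T ≤ r ≤ R`` and
#:     normalise by the shell volume.  Physically the cleanest reading:
#:     tumour cells live in the shell only, and ``f → f_max`` as ``ρ → ∞``.
#: ``"include-core"``
#:     Credit the T-cell core volume as fully exposed (σ/σ_T = 1 inside) and
#:     normalise by the full sphere volume ``R³``.  Also has the correct
#:     ``ρ → ∞`` limit.
#: ``"sphere"``
#:     Shell integral normalised by the full sphere volume ``R³`` with no
#:     credit for the core.  This variant vanishes as ``ρ → ∞`` (the core is
#:     treated as dead volume), which is unphysical in that limit, but it is
#:     the only one of the three able to interpolate the published in-vivo
#:     dose–response points exactly; it is retained as a documented
#:     reconstruction of the original curve fits.
CONVENTIONS = ("shell", "include-core", "sphere")


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class KillModelParams:
    """Physical parameters of the kill-fraction model.

    Parameters
    ----------
    f_kill_max : float
        Kill fraction under uniform exposure (no diffusion gradient),
        dimensionless, in [0, 1].
    L : float
        Diffusion penetration distance sqrt(D/λ), µm.
    d_T : float
        Geometric-mean T-cell diameter, µm (default 3).
    d_C : float
        Geometric-mean tumour-cell diameter, µm (default 7).
    """

    f_kill_max: float
    L: float
    d_T: float = 3.0
    d_C: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_kill_max <= 1.0) or not np.isfinite(self.f_kill_max):
            raise DomainError(
                f"f_kill_max must lie in [0, 1], got {self.f_kill_max!r}"
            )
        _check_positive(L=self.L, d_T=self.d_T, d_C=self.d_C)

    @property
    def R_T(self) -> float:
        """Equivalent T-cell radius, µm."""
        return self.d_T / 2.0

    @property
    def R_C(self) -> float:
        """Equivalent tumour-cell radius, µm."""
        return self.d_C / 2.0


@dataclass(frozen=True)
class ConcentrationField:
    """Normalised steady-state concentration field around one T cell.

    The field is ``σ(r)/σ_T = (R_T/r)·exp(−(r−R_T)/L)``, i.e. normalised to 1
    at the T-cell membrane ``r = R_T``.
    """

    R_T: float
    L: float

    def __post_init__(self) -> None:
        _check_positive(R_T=self.R_T, L=self.L)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One observed (ratio, kill fraction) pair."""

    rho: float
    f_kill: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho) or self.rho < 0:
            raise DomainError(f"rho must be a non-negative ratio, got {self.rho!r}")
        if not (0.0 <= self.f_kill <= 1.0):
            raise DomainError(f"f_kill must lie in [0, 1], got {self.f_kill!r}")


@dataclass(frozen=True)
class PenetrationReference:
    """Reference-compound data for scaling the penetration distance.

    ``L = sqrt(D/λ)``; the diffusivity of a compact molecule scales with its
    hydrodynamic (Stokes–Einstein) radius, i.e. with molecular weight to the
    power ``−mass_exponent`` (default 1/3).  Given a reference compound with
    measured ``(L_ref, lambda_ref, M_ref)``, the target compound's
    penetration distance follows from the uptake-rate and molecular-weight
    ratios.
    """

    L_ref: float
    lambda_ref: float
    M_ref: float
    lambda_target: float
    M_target: float
    mass_exponent: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        _check_positive(
            L_ref=self.L_ref,
            lambda_ref=self.lambda_ref,
            M_ref=self.M_ref,
            lambda_target=self.lambda_target,
            M_target=self.M_target,
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit of (f_kill_max, L)."""

    params: KillModelParams
    r_squared: float
    p_value_L: float
    residuals: tuple[float, ...]
    n_points: int
    converged: bool
    convention: str = "shell"
    se_L: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "f_kill_max": self.params.f_kill_max,
            "L_um": self.params.L,
            "r_squared": self.r_squared,
            "p_value_L": self.p_value_L,
            "n_points": self.n_points,
            "converged": self.converged,
            "convention": self.convention,
        }


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def concentration_ratio(r, field: ConcentrationField):
    """Normalised concentration σ(r)/σ_T at radius ``r`` (µm).

    Equals 1 at the membrane ``r = R_T`` and decays as ``(R_T/r)e^{−(r−R_T)/L}``
    outward.  Accepts scalars or arrays; radii inside the T cell raise
    :class:`~cytodiff.errors.DomainError`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < field.R_T * (1 - 1e-12)):
        raise DomainError("r < R_T lies inside the T cell; the field is undefined there")
    out = (field.R_T / r) * np.exp(-(r - field.R_T) / field.L)
    return out if out.ndim else float(out)


def interaction_radius(rho, d_T: float = 3.0, d_C: float = 7.0):
    """Radius of the sphere containing one T cell plus its 1/ρ tumour cells.

    ``R = (R_T³ + R_C³/ρ)^{1/3}`` with radii = diameter/2.  ``R → R_T`` as
    ``ρ → ∞``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(~np.isfinite(rho)) or np.any(rho <= 0):
        raise DomainError("rho must be finite and > 0")
    _check_positive(d_T=d_T, d_C=d_C)
    R_T, R_C = d_T / 2.0, d_C / 2.0
    out = np.cbrt(R_T**3 + R_C**3 / rho)
    return out if out.ndim else float(out)


def _exposure_integral(R_T, R, L):
    """``3 R_T ∫_{R_T}^{R} r e^{−(r−R_T)/L} dr`` (volume integral of σ/σ_T
    over the shell, divided by 4π/3).

    The antiderivative of ``r e^{−(r−R_T)/L}`` is ``−L e^{−(r−R_T)/L}(r+L)``;
    the bracket is evaluated with ``expm1`` to stay accurate when the shell is
    thin compared to L (large ρ).
    """
    delta = R - R_T
    bracket = (R + L) * (-np.expm1(-delta / L)) - delta
    return 3.0 * R_T * L * bracket


def kill_fraction(rho, params: KillModelParams, convention: str = "shell"):
    """Predicted tumour-kill fraction at T-cell : tumour-cell ratio ``ρ``.

    Closed form of ``f_max`` times the volume average of
    :func:`concentration_ratio` over the interaction sphere, under the chosen
    normalisation ``convention`` (see :data:`CONVENTIONS`).  Vectorised in
    ``rho``.
    """
    if convention not in CONVENTIONS:
        raise DomainError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(~np.isfinite(rho_arr)) or np.any(rho_arr <= 0):
        raise DomainError("rho must be finite and > 0")
    R_T, R_C, L = params.R_T, params.R_C, params.L
    R = np.cbrt(R_T**3 + R_C**3 / rho_arr)
    integral = _exposure_integral(R_T, R, L)
    shell_vol = R_C**3 / rho_arr  # R³ − R_T³, exact by construction
    if convention == "shell":
        frac = integral / shell_vol
    elif convention == "include-core":
        frac = (R_T**3 + integral) / (R_T**3 + shell_vol)
    else:  # sphere
        frac = integral / (R_T**3 + shell_vol)
    out = params.f_kill_max * np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


def predict_curve(
    params: KillModelParams,
    rho_values: Iterable[float],
    convention: str = "shell",
    label: str = "model",
) -> list[DoseResponsePoint]:
    """Element-wise :func:`kill_fraction` over a grid, order preserved."""
    rho_values = list(rho_values)
    if not rho_values:
        return []
    f = np.atleast_1d(kill_fraction(np.asarray(rho_values, float), params, convention))
    return [DoseResponsePoint(r, fk, label) for r, fk in zip(rho_values, f)]


def penetration_from_reference(ref: PenetrationReference) -> float:
    """Penetration distance of the target compound scaled from a reference.

    ``L_target = L_ref · sqrt((λ_ref/λ_target) · (M_ref/M_target)^mass_exponent)``,
    i.e. ``L = sqrt(D/λ)`` with ``D ∝ M^{−mass_exponent}``.
    """
    return ref.L_ref * math.sqrt(
        (ref.lambda_ref / ref.lambda_target)
        * (ref.M_ref / ref.M_target) ** ref.mass_exponent
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_L_STARTS = (1.0, 10.0, 100.0, 1000.0)
_L_BOUNDS = (1e-3, 1e7)


def _shape(rho, L, d_T, d_C, convention):
    """kill_fraction with f_kill_max = 1 (the purely geometric factor)."""
    p = KillModelParams(1.0, L, d_T, d_C)
    return kill_fraction(rho, p, convention)


def _two_point_exact(rho, f, d_T, d_C, convention, f_max_cap=1.0):
    """Solve the 2×2 system f_i = f_max·g(ρ_i, L) exactly, if a solution with
    0 < f_max ≤ f_max_cap and L in bounds exists.  Returns (f_max, L) or None.

    f_max cancels from the ratio, leaving h(L) = f₁·g(ρ₂,L) − f₂·g(ρ₁,L) = 0,
    which is solved by bracketing + Brent on a log-L grid.
    """
    (r1, r2), (f1, f2) = rho, f

    def h(logL):
        L = math.exp(logL)
        return f1 * _shape(r2, L, d_T, d_C, convention) - f2 * _shape(
            r1, L, d_T, d_C, convention
        )

    grid = np.linspace(math.log(_L_BOUNDS[0]), math.log(_L_BOUNDS[1]), 200)
    vals = np.array([h(x) for x in grid])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    for i in idx:
        try:
            logL = optimize.brentq(h, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15)
        except ValueError:  # pragma: no cover - bracket degenerate
            continue
        L = math.exp(logL)
        g1 = _shape(r1, L, d_T, d_C, convention)
        if g1 <= 0:
            continue
        f_max = f1 / g1
        if 0.0 < f_max <= f_max_cap * (1.0 + 1e-12):
            return min(f_max, f_max_cap), L
    return None


def fit_two_point_exact(
    p1: DoseResponsePoint,
    p2: DoseResponsePoint,
    d_T: float = 3.0,
    d_C: float = 7.0,
    convention: str = "sphere",
    f_max_cap: float = math.inf,
) -> tuple[float, float, tuple[float, float]]:
    """Exactly-identified solve of ``(f_max, L)`` through two observed points.

    With two points and two free parameters the model either interpolates the
    data exactly or not at all, so this is a root-finding problem rather than
    a least-squares one: ``f_max`` cancels from the ratio of the two model
    values, leaving a single equation in ``L``.

    The exposure scale ``f_max`` is left uncapped by default: when the model
    shape under-predicts the more saturated point, the interpolating scale can
    exceed 1, in which case it is an effective amplitude rather than a
    fraction.  The default convention is ``"sphere"`` because it is the only
    normalisation whose attainable shape ratios cover published in-vivo
    dose–response pairs (see module docstring and :data:`CONVENTIONS`).

    Returns ``(f_max, L, residuals)``; raises
    :class:`~cytodiff.errors.DomainError` when no interpolating solution
    exists within the L bounds.
    """
    if convention not in CONVENTIONS:
        raise DomainError(f"unknown convention {convention!r}")
    rho = (p1.rho, p2.rho)
    f = (p1.f_kill, p2.f_kill)
    if rho[0] == rho[1]:
        raise DegenerateDesignError("the two points must have distinct rho")
    sol = _two_point_exact(rho, f, d_T, d_C, convention, f_max_cap=f_max_cap)
    if sol is None:
        raise DomainError(
            "no interpolating (f_max, L) exists for these two points under "
            f"the {convention!r} convention"
        )
    f_max, L = sol
    res = tuple(
        f_max * _shape(r, L, d_T, d_C, convention) - fk for r, fk in zip(rho, f)
    )
    return f_max, L, res


def fit_kill_model(
    data: Sequence[DoseResponsePoint],
    d_T: float = 3.0,
    d_C: float = 7.0,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    convention: str = "shell",
) -> FitResult:
    """Bounded least-squares fit of ``(f_kill_max, L)`` to dose–response data.

    ``d_T`` and ``d_C`` are held fixed.  The optimiser is multi-started over
    ``L ∈ {1, 10, 100, 1000}`` µm (``f_kill_max`` started at 0.5) because the
    objective can be nearly flat in ``L`` for saturating data.  With exactly
    two distinct points the system is exactly identified and solved by root
    bracketing first, falling back to least squares when no interpolating
    solution exists within the parameter bounds.

    The p-value for ``L`` is a two-sided t test of ``L̂ / SE(L̂)`` with the
    standard error taken from the Gauss–Newton approximation of the parameter
    covariance and ``n − 2`` degrees of freedom.
    """
    data = list(data)
    if len(data) < 2:
        raise InsufficientDataError(
            f"need at least 2 dose-response points, got {len(data)}"
        )
    rho = np.array([p.rho for p in data], float)
    f_obs = np.array([p.f_kill for p in data], float)
    if np.any(rho <= 0):
        raise DomainError("all fitted points must have rho > 0")
    if np.unique(rho).size < 2:
        raise DegenerateDesignError("all rho values identical; L is unidentifiable")

    f_bounds, L_bounds = bounds if bounds is not None else ((0.0, 1.0), _L_BOUNDS)

    def residual_fn(theta):
        f_max, L = theta
        return kill_fraction(rho, KillModelParams(min(max(f_max, 0.0), 1.0), L, d_T, d_C), convention) - f_obs

    best = None
    if len(data) == 2:
        exact = _two_point_exact(rho, f_obs, d_T, d_C, convention)
        if exact is not None:
            f_max, L = exact
            theta = np.array([f_max, L])
            best = optimize.OptimizeResult(
                x=theta, fun=residual_fn(theta), success=True, jac=None
            )

    if best is None:
        lower = np.array([f_bounds[0], L_bounds[0]])
        upper = np.array([f_bounds[1], L_bounds[1]])
        for L0 in _L_STARTS:
            x0 = np.array([0.5, np.clip(L0, *L_bounds)])
            sol = optimize.least_squares(
                residual_fn,
                x0,
                bounds=(lower, upper),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            if best is None or np.sum(sol.fun**2) < np.sum(best.fun**2) - 0.0:
                best = sol

    f_max_hat, L_hat = float(best.x[0]), float(best.x[1])
    residuals = np.asarray(residual_fn(best.x), float)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    n, dof = len(data), len(data) - 2
    se_L = p_value = float("nan")
    if dof > 0:
        # Gauss-Newton covariance from a central-difference Jacobian at the optimum
        jac = np.empty((n, 2))
        eps = np.array([1e-7, max(1e-6 * L_hat, 1e-9)])
        for j in range(2):
            step = np.zeros(2)
            step[j] = eps[j]
            hi = np.clip(best.x + step, [0.0, L_bounds[0]], [1.0, L_bounds[1]])
            lo = np.clip(best.x - step, [0.0, L_bounds[0]], [1.0, L_bounds[1]])
            jac[:, j] = (residual_fn(hi) - residual_fn(lo)) / (hi[j] - lo[j])
        jtj = jac.T @ jac
        sigma2 = ss_res / dof
        try:
            cov = sigma2 * np.linalg.inv(jtj)
            se_L = float(np.sqrt(max(cov[1, 1], 0.0)))
            if se_L > 0:
                t_stat = L_hat / se_L
                p_value = float(2.0 * stats.t.sf(abs(t_stat), dof))
        except np.linalg.LinAlgError:
            pass

    params = KillModelParams(min(max(f_max_hat, 0.0), 1.0), L_hat, d_T, d_C)
    return FitResult(
        params=params,
        r_squared=r_squared,
        p_value_L=p_value,
        residuals=tuple(residuals.tolist()),
        n_points=n,
        converged=bool(best.success),
        convention=convention,
        se_L=se_L,
    )
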