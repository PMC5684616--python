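"""Continuous compartment: nondimensional oxygen reaction-diffusion.

Oxygen o(x, y, t) diffuses with coefficient D_o, decays at rate alpha_o
and is consumed at rate gamma_o at sites holding a tumour cell:

    do/dt = D_o * laplacian(o) - c(i,j) * gamma_o - alpha_o * o

The equation is nondimensionalized by the maximum concentration o_max,
the iteration time tau and the domain length L, and advanced one
iteration per automaton step with the Peaceman-Rachford alternating
directions implicit (ADI) scheme. The domain boundary is held at the
maximum concentration (Dirichlet), emulating periodically refreshed
culture medium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "OxygenParams",
    "NDOxygenParams",
    "OxygenField",
    "nondimensionalize",
    "adi_step",
    "steady_state_relative_residual",
]


@dataclass(frozen=True)
class OxygenParams:
    """Dimensional oxygen parameters.

    Attributes
    ----------
    D_o_cm2_s : float
        Diffusion coefficient in cm^2/s. Not reported by the source
        study; the default 1e-5 cm^2/s is the standard oxygen value in
        the hybrid discrete-continuum literature. Override freely.
    alpha_o_nd : float
        Natural decay rate, already nondimensional (default 0.0125).
    gamma_o_M_cell_s : float
        Per-cell consumption rate, M cell^-1 s^-1 (default 6.25e-17).
    o_max_M_cm3 : float
        Maximum (boundary) concentration used as the concentration
        scale (default 6.7e-6); only the nondimensional field is used
        downstream, so this acts as an opaque scale constant.
    o_deadly : float
        Nondimensional death threshold in [0, 1). Cells at sites with
        oxygen strictly below it die. Default 0: hypoxic death disabled,
        since with Dirichlet boundaries at o_max the small spheroids
        simulated here are treated as oxygen-sufficient.
    tau_h, L_mm : float, optional
        Iteration time and domain length; when ``None`` they are taken
        from the simulation config so there is a single source of truth.
    kappa_star_override : float, optional
        Directly sets the nondimensional per-cell consumption, bypassing
        the volumetric conversion (see :func:`nondimensionalize`).
    """

    D_o_cm2_s: float = 1e-5
    alpha_o_nd: float = 0.0125
    gamma_o_M_cell_s: float = 6.25e-17
    o_max_M_cm3: float = 6.7e-6
    o_deadly: float = 0.0
    tau_h: Optional[float] = None
    L_mm: Optional[float] = None
    kappa_star_override: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("D_o_cm2_s", "alpha_o_nd", "gamma_o_M_cell_s", "o_max_M_cm3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not 0 <= self.o_deadly < 1:
            raise ValueError(f"o_deadly must be in [0, 1), got {self.o_deadly}")
        for name in ("tau_h", "L_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class NDOxygenParams:
    """Nondimensional PDE coefficients (per iteration tau, domain length 1)."""

    D_star: float
    alpha_star: float
    kappa_star: float


def nondimensionalize(
    params: OxygenParams,
    tau_h: Optional[float] = None,
    L_mm: Optional[float] = None,
    cell_size_um: float = 18.0,
) -> NDOxygenParams:
    """Scale the dimensional parameters by o_max, tau and L.

    D_star = D_o * tau / L^2 (time in seconds, length in cm).
    alpha_star passes through (the decay rate is given nondimensional).
    kappa_star converts the per-cell molar sink to o_max units assuming
    one cell consumes from its own site volume h^3:
    kappa_star = gamma_o * tau_s / (o_max * h_cm^3), unless overridden.
    """
    tau_h = params.tau_h if params.tau_h is not None else tau_h
    L_mm = params.L_mm if params.L_mm is not None else L_mm
    if tau_h is None or tau_h <= 0:
        raise ValueError(f"tau_h must be set and > 0, got {tau_h}")
    if L_mm is None or L_mm <= 0:
        raise ValueError(f"L_mm must be set and > 0, got {L_mm}")
    if cell_size_um <= 0:
        raise ValueError(f"cell_size_um must be > 0, got {cell_size_um}")
    tau_s = tau_h * 3600.0
    L_cm = L_mm / 10.0
    D_star = params.D_o_cm2_s * tau_s / L_cm**2
    alpha_star = params.alpha_o_nd
    if params.kappa_star_override is not None:
        kappa_star = params.kappa_star_override
    else:
        h_cm = cell_size_um * 1e-4
        kappa_star = params.gamma_o_M_cell_s * tau_s / (params.o_max_M_cm3 * h_cm**3)
    nd = NDOxygenParams(D_star=D_star, alpha_star=alpha_star, kappa_star=kappa_star)
    for name in ("D_star", "alpha_star", "kappa_star"):
        v = getattr(nd, name)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    return nd


class OxygenField:
    """Nondimensional oxygen concentration on the simulation lattice."""

    def __init__(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"field must be square 2D, got shape {values.shape}")
        self.values = values

    @classmethod
    def uniform(cls, n: int, value: float = 1.0) -> "OxygenField":
        return cls(np.full((n, n), float(value)))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "OxygenField":
        return OxygenField(self.values.copy())


def _apply_reaction_half(
    o: np.ndarray, occupied: np.ndarray, nd: NDOxygenParams
) -> np.ndarray:
    """Half-iteration explicit reaction update, clamped at 0."""
    o = o - 0.5 * nd.alpha_star * o
    o[occupied] -= 0.5 * nd.kappa_star
    np.clip(o, 0.0, None, out=o)
    return o


def _fix_boundary(o: np.ndarray) -> None:
    o[0, :] = 1.0
    o[-1, :] = 1.0
    o[:, 0] = 1.0
    o[:, -1] = 1.0


def adi_step(
    field: OxygenField,
    occupied: np.ndarray,
    nd: NDOxygenParams,
) -> OxygenField:
    """Advance the oxygen field by one iteration (nondimensional dt = 1).

    Reaction terms (decay everywhere, consumption at occupied sites) are
    applied by first-order operator splitting: half before and half
    after a Peaceman-Rachford diffusion step (implicit rows, then
    implicit columns; each half-step solves one constant tridiagonal
    system with many right-hand sides). Boundaries are re-locked at 1
    and the result is clamped to [0, 1].
    """
    o = field.values
    n = field.n
    if occupied.shape != o.shape:
        raise ValueError(
            f"occupancy shape {occupied.shape} != field shape {o.shape}"
        )
    if n < 3:
        # No interior: a pure-boundary domain stays locked at 1.
        out = o.copy()
        _fix_boundary(out)
        return OxygenField(out)

    o = _apply_reaction_half(o.copy(), occupied, nd)
    _fix_boundary(o)

    dx = 1.0 / (n - 1)
    lam = nd.D_star * 0.5 / dx**2  # dt/2 with dt = 1
    m = n - 2
    ab = np.zeros((3, m))
    ab[0, 1:] = -lam
    ab[1, :] = 1.0 + 2.0 * lam
    ab[2, :-1] = -lam

    # Diffuse the deviation w = o - 1 (zero Dirichlet boundary): the
    # uniform-1 field maps to rhs = 0 and survives the solves exactly.
    w = o - 1.0

    # Half-step 1: implicit along rows (x), explicit along columns (y).
    interior = w[1:-1, 1:-1]
    rhs = interior + lam * (w[:-2, 1:-1] - 2.0 * interior + w[2:, 1:-1])
    w1 = np.zeros_like(w)
    w1[1:-1, 1:-1] = solve_banded((1, 1), ab, rhs.T).T

    # Half-step 2: implicit along columns (y), explicit along rows (x).
    interior = w1[1:-1, 1:-1]
    rhs = interior + lam * (w1[1:-1, :-2] - 2.0 * interior + w1[1:-1, 2:])
    u2 = np.ones_like(o)
    u2[1:-1, 1:-1] = 1.0 + solve_banded((1, 1), ab, rhs)

    u2 = _apply_reaction_half(u2, occupied, nd)
    np.clip(u2, 0.0, 1.0, out=u2)
    _fix_boundary(u2)
    return OxygenField(u2)


def steady_state_relative_residual(
    field: OxygenField,
    occupied: np.ndarray,
    nd: NDOxygenParams,
) -> float:
    """Max-norm one-step change over max-norm of the field (0 iff stationary)."""
    nxt = adi_step(field, occupied, nd)
    denom = float(np.max(np.abs(field.values)))
    if denom == 0.0:
        denom = 1.0
    return float(np.max(np.abs(nxt.values - field.values)) / denom)
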