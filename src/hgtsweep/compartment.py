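"""Deterministic compartment model of a horizontally transferable allele.

A community of fixed size ``N`` is split into carriers (fraction ``C``) and
non-carriers (``1 - C``) of a beneficial allele.  Carriers have fitness
``1 + s``; non-carriers acquire the allele horizontally with per-capita
probability ``r * C`` per generation; a fraction ``m`` of the community is
replaced each generation by allele-free immigrants.  The carrier fraction
obeys

    dC/dt = s C (1 - C) / (1 + s C) + r C (1 - C) - m C .

Without migration the fixed points are C* = 0 (unstable) and C* = 1
(stable): the allele always fixes.  With migration and r ~ 0 the stable
interior equilibrium is the migration-selection balance

    C* = (s - m) / ((m + 1) s),

which exists only while selection outpowers migration (s > m).  The
community-level rate of transfer events, the horizontal gene flux, is
``r C (1 - C) N``; its time integral counts expected transfer events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import SweepParams, TwoPatchParams

__all__ = [
    "DomainError",
    "IntegrationError",
    "SteadyState",
    "Trajectory",
    "drift_field",
    "steady_states",
    "integrate",
    "gene_flux",
    "steady_state_flux",
    "cumulative_flux",
    "two_patch_integrate",
]

#: relative tolerance of the adaptive solver
RTOL = 1e-8
#: absolute tolerance of the adaptive solver
ATOL = 1e-12
#: how far outside [0, 1] a numerical solution may stray before it is an error
ESCAPE_TOL = 1e-6
#: minimum number of output-grid points used for flux integration
MIN_GRID = 10_001


class DomainError(ValueError):
    """A state variable lies outside its admissible domain."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or the solution escaped [0, 1]."""


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the carrier-fraction dynamics.

    ``stability`` is determined by the sign of the drift-field derivative at
    the fixed point ("neutral" when the derivative vanishes, e.g. in the
    fully degenerate s = r = m = 0 model where every point is a fixed
    point).  ``admissible`` flags whether the value lies in [0, 1]; roots
    outside the unit interval are reported flagged rather than dropped.
    """

    value: float
    stability: str  # "stable" | "unstable" | "neutral"
    admissible: bool


@dataclass
class Trajectory:
    """Time series of the carrier fraction and the horizontal gene flux.

    ``flux`` is the instantaneous gene flux r C (1-C) N (events per
    generation); ``cumulative_flux`` its running left-rectangle integral
    (expected transfer events since t = 0).
    """

    times: np.ndarray
    C: np.ndarray
    carriers_count: np.ndarray
    flux: np.ndarray
    cumulative_flux: np.ndarray
    params: SweepParams | None = None
    migration_on: bool | None = None
    dense: object | None = field(default=None, repr=False)  # scipy OdeSolution

    def __post_init__(self) -> None:
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


def _migration_flag(p: SweepParams, migration_on: bool | None) -> bool:
    return (p.m > 0) if migration_on is None else bool(migration_on)


def _drift(C, p: SweepParams, m: float):
    """Drift field without domain checks; C may be scalar or array."""
    return p.s * C * (1.0 - C) / (1.0 + p.s * C) + p.r * C * (1.0 - C) - m * C


def _drift_derivative(C: float, p: SweepParams, m: float) -> float:
    s, r = p.s, p.r
    u = C - C * C
    sel = s * ((1.0 - 2.0 * C) * (1.0 + s * C) - s * u) / (1.0 + s * C) ** 2
    return sel + r * (1.0 - 2.0 * C) - m


def drift_field(C, p: SweepParams, migration_on: bool | None = None):
    """Rate of change of the carrier fraction, dC/dt, per generation.

    Parameters
    ----------
    C : float or array_like
        Carrier fraction(s) in [0, 1].
    p : SweepParams
    migration_on : bool, optional
        Include the -m*C immigration term.  Defaults to ``p.m > 0``.
    """
    Ca = np.asarray(C, dtype=float)
    if np.any(Ca < -1e-12) or np.any(Ca > 1.0 + 1e-12):
        raise DomainError(f"carrier fraction outside [0, 1]: {C!r}")
    m = p.m if _migration_flag(p, migration_on) else 0.0
    out = _drift(np.clip(Ca, 0.0, 1.0), p, m)
    return float(out) if np.isscalar(C) else out


def _classify(value: float, p: SweepParams, m: float) -> SteadyState:
    d = _drift_derivative(value, p, m)
    if d < 0:
        stab = "stable"
    elif d > 0:
        stab = "unstable"
    else:
        stab = "neutral"
    return SteadyState(value, stab, 0.0 <= value <= 1.0)


def steady_states(
    p: SweepParams, migration_on: bool | None = None
) -> list[SteadyState]:
    """All fixed points of the drift field, with stability and admissibility.

    Without migration: {0 (unstable), 1 (stable)}.  With migration the
    interior root is the migration-selection balance; for r = 0 the closed
    form (s - m)/((m + 1) s) is used, otherwise the root is found
    numerically.  When migration overpowers selection (s + r <= m) the
    would-be interior root lies outside [0, 1] and is returned flagged as
    inadmissible.
    """
    m = p.m if _migration_flag(p, migration_on) else 0.0
    if p.s == 0.0 and p.r == 0.0 and m == 0.0:
        # degenerate flat field: every point is a (neutral) fixed point
        return [SteadyState(float("nan"), "neutral", True)]

    roots = [_classify(0.0, p, m)]
    if m == 0.0:
        roots.append(_classify(1.0, p, m))
        return roots

    # interior balance: root of g(C) = s(1-C)/(1+sC) + r(1-C) - m
    def g(C: float) -> float:
        return p.s * (1.0 - C) / (1.0 + p.s * C) + p.r * (1.0 - C) - m

    if p.r == 0.0:
        if p.s > 0.0:
            roots.append(_classify((p.s - m) / ((m + 1.0) * p.s), p, m))
    elif g(0.0) > 0.0:  # s + r > m: root inside (0, 1)
        c = brentq(g, 0.0, 1.0, xtol=1e-15, rtol=8.9e-16)
        roots.append(_classify(c, p, m))
    elif p.s > 0.0:
        # migration overpowers selection; report the r~0 closed form, flagged
        roots.append(_classify((p.s - m) / ((m + 1.0) * p.s), p, m))
    return roots


def gene_flux(C, p: SweepParams):
    """Horizontal gene flux r C (1 - C) N, in transfer events per generation."""
    Ca = np.asarray(C, dtype=float)
    if np.any(Ca < -1e-12) or np.any(Ca > 1.0 + 1e-12):
        raise DomainError(f"carrier fraction outside [0, 1]: {C!r}")
    Ca = np.clip(Ca, 0.0, 1.0)
    out = p.r * Ca * (1.0 - Ca) * p.N
    return float(out) if np.isscalar(C) else out


def steady_state_flux(p: SweepParams, migration_on: bool | None = None) -> float:
    """Gene flux at the stable steady state of the dynamics.

    Without migration the allele fixes (C* = 1) and the steady flux is 0.
    With migration overpowering selection no interior equilibrium exists;
    0 is returned with a warning.
    """
    m_on = _migration_flag(p, migration_on)
    stable = [
        ss
        for ss in steady_states(p, migration_on=m_on)
        if ss.admissible and ss.stability == "stable" and np.isfinite(ss.value)
    ]
    interior = [ss for ss in stable if 0.0 < ss.value < 1.0]
    if interior:
        return gene_flux(interior[0].value, p)
    if m_on and p.m > 0 and not interior:
        warnings.warn(
            "no interior steady state (migration overpowers selection); "
            "steady-state flux is 0",
            stacklevel=2,
        )
    return 0.0


def integrate(
    p: SweepParams,
    t_end: float,
    migration_on: bool | None = None,
    output_grid: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the carrier-fraction ODE forward from C(0) = p.C0.

    Uses an adaptive solver (LSODA, rtol 1e-8 / atol 1e-12) with dense
    output.  The returned trajectory is sampled on ``output_grid`` if given,
    otherwise on a uniform grid fine enough that halving the step changes
    the cumulative flux by < 0.5 %.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    m = p.m if _migration_flag(p, migration_on) else 0.0

    sol = solve_ivp(
        lambda t, y: _drift(np.clip(y, 0.0, 1.0), p, m),
        (0.0, float(t_end)),
        [p.C0],
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    def sample(times: np.ndarray) -> np.ndarray:
        C = sol.sol(times)[0]
        if C.min() < -ESCAPE_TOL or C.max() > 1.0 + ESCAPE_TOL:
            raise IntegrationError(
                f"solution escaped [0, 1]: range [{C.min():.3e}, {C.max():.3e}]"
            )
        return np.clip(C, 0.0, 1.0)

    if output_grid is not None:
        times = np.asarray(output_grid, dtype=float)
        C = sample(times)
        flux = gene_flux(C, p)
        cum = _left_rectangle(times, flux)
    else:
        npts = MIN_GRID
        prev_total = None
        while True:
            times = np.linspace(0.0, float(t_end), npts)
            C = sample(times)
            flux = gene_flux(C, p)
            cum = _left_rectangle(times, flux)
            total = cum[-1]
            if prev_total is not None:
                scale = max(abs(total), abs(prev_total))
                if scale == 0.0 or abs(total - prev_total) < 0.005 * scale:
                    break
            if npts > 4 * 10**6:  # refinement safety valve
                break
            prev_total = total
            npts = 2 * npts - 1

    return Trajectory(
        times=times,
        C=C,
        carriers_count=C * p.N,
        flux=flux,
        cumulative_flux=cum,
        params=p,
        migration_on=(m > 0),
        dense=sol.sol,
    )


def _left_rectangle(times: np.ndarray, flux: np.ndarray) -> np.ndarray:
    cum = np.empty_like(flux)
    cum[0] = 0.0
    np.cumsum(flux[:-1] * np.diff(times), out=cum[1:])
    return cum


def cumulative_flux(traj: Trajectory) -> float:
    """Expected number of transfer events over the trajectory.

    Left-endpoint rectangle rule on the trajectory grid.  If the trajectory
    carries a dense solution and its parameters, the grid is refined by step
    halving until the total changes by < 0.5 %.
    """
    if len(traj.times) < 2:
        raise ValueError("cumulative flux needs a trajectory with >= 2 points")
    total = float(np.sum(traj.flux[:-1] * np.diff(traj.times)))
    if traj.dense is None or traj.params is None:
        return total
    p = traj.params
    t0, t1 = traj.times[0], traj.times[-1]
    npts = len(traj.times)
    while npts <= 4 * 10**6:
        npts = 2 * npts - 1
        times = np.linspace(t0, t1, npts)
        flux = gene_flux(np.clip(traj.dense(times)[0], 0.0, 1.0), p)
        refined = float(np.sum(flux[:-1] * np.diff(times)))
        scale = max(abs(refined), abs(total))
        if scale == 0.0 or abs(refined - total) < 0.005 * scale:
            return refined
        total = refined
    return total


def two_patch_integrate(
    p2: TwoPatchParams,
    t_end: float,
    output_grid: np.ndarray | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Integrate the coupled focal-patch / external-environment model.

    Each patch runs the within-patch dynamics (selection with its own s,
    plus horizontal transfer); cells swap between the patches at per-capita
    rate ``exchange`` from the focal side, with the return flow scaled by
    the size ratio so that both patch sizes are conserved:

        dC_F/dt = g(C_F; s)     + e (C_E - C_F)
        dC_E/dt = g(C_E; s_env) + (e / rho) (C_F - C_E)

    where rho is the environment/focal size ratio.  A large environment
    (rho >> 1) reproduces the one-patch migration model with m = e; a small
    environment merges the patches into a single patch in which the allele
    fixes.  rho = 0 (no environment) decouples the patches.
    """
    pf = p2.focal
    e = p2.exchange
    rho = p2.env_size_ratio
    back = (e / rho) if (rho > 0 and e > 0) else 0.0

    def rhs(t, y):
        cf, ce = np.clip(y, 0.0, 1.0)
        gf = pf.s * cf * (1 - cf) / (1 + pf.s * cf) + pf.r * cf * (1 - cf)
        ge = p2.s_env * ce * (1 - ce) / (1 + p2.s_env * ce) + pf.r * ce * (1 - ce)
        return [gf + e * (ce - cf), ge + back * (cf - ce)]

    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        [pf.C0, p2.C0_env],
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"two-patch solver failed: {sol.message}")

    times = (
        np.asarray(output_grid, dtype=float)
        if output_grid is not None
        else np.linspace(0.0, float(t_end), MIN_GRID)
    )
    Y = sol.sol(times)
    if Y.min() < -ESCAPE_TOL or Y.max() > 1.0 + ESCAPE_TOL:
        raise IntegrationError(
            f"two-patch solution escaped [0, 1]: range [{Y.min():.3e}, {Y.max():.3e}]"
        )
    Y = np.clip(Y, 0.0, 1.0)

    trajs = []
    for row, N_patch in ((Y[0], float(pf.N)), (Y[1], pf.N * rho)):
        flux = pf.r * row * (1.0 - row) * N_patch
        trajs.append(
            Trajectory(
                times=times,
                C=row,
                carriers_count=row * N_patch,
                flux=flux,
                cumulative_flux=_left_rectangle(times, flux),
            )
        )
    return trajs[0], trajs[1]
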