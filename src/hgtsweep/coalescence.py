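"""Backward-in-time pair coalescence under a forward horizontal sweep.

Two homologous loci are sampled at the end of a forward sweep (carrier
dynamics C(t) from :mod:`hgtsweep.compartment`) and traced backward to
t = 0.  The pair occupies one of six states:

====  =========================================================
S11   two distinct individuals, both carriers
S00   two distinct individuals, both non-carriers
S01   two distinct individuals, one carrier and one non-carrier
S1    loci coalesced in a single carrier
S0    loci coalesced in a single non-carrier
SM    at least one locus in a migrant outside the patch
====  =========================================================

Backward per-generation transition rates, with class frequencies supplied
by the forward solution:

* within-class pair coalescence at 1/(N x) for a class of frequency x
  (carrier pairs S11 -> S1 at 1/(N C); non-carrier pairs S00 -> S0 at
  1/(N (1-C)));
* a non-carrier lineage of a non-coalesced pair is a fresh immigrant at
  rate m/(1-C) (all immigrants lack the allele and carry unique genomes),
  sending the pair to SM;
* for the *background* locus only, a lineage in a carrier switches to the
  non-carrier class at rate r(1-C): forward transfer converts a
  non-carrier in place, keeping its background genome (S11 -> S01 at
  2r(1-C), S01 -> S00 at r(1-C));
* for the *focal* locus a transfer recipient's allele traces to the donor
  -- another carrier -- so focal lineages never leave the carrier class;
  the donor jump adds a second-order coalescence term 2r(1-C)/(N C) to
  S11 -> S1 (numerically negligible).

Coalesced states (S1, S0) and SM are absorbing: identity is decided at the
first coalescence, so the later (earlier forward-time) history of a
coalesced pair is irrelevant.  A pair is identical at sampling iff it
coalesced before t = 0 or both lineages sit in the carrier class at t = 0
(the founding carriers are a single clone); initial non-carriers and every
immigrant are unique.  Hence F = P(S1) + P(S0) + P(S11) at t = 0, the
diversity is D = 1/F (order-2 Hill number of an effective composition),
and DR = D_bg / D_f = F_f / F_b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .compartment import IntegrationError, Trajectory, integrate
from .params import SweepParams

__all__ = [
    "STATES",
    "PairStateDist",
    "CoalescenceResult",
    "sample_pair",
    "backward_rates",
    "solve_pair",
    "diversity_ratio",
]

#: state order used for all probability vectors and rate tables
STATES = ("S11", "S00", "S01", "S1", "S0", "SM")
_S11, _S00, _S01, _S1, _S0, _SM = range(6)

#: probability-conservation tolerance of the backward solver
CONS_TOL = 1e-9


@dataclass
class PairStateDist:
    """Probability distribution of a sampled pair over the six states."""

    probabilities: np.ndarray
    locus_kind: str  # "focal" | "background"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (6,):
            raise ValueError("need exactly six state probabilities")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"not a probability vector: {p!r}")
        self.probabilities = p

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[STATES.index(state)])


@dataclass(frozen=True)
class CoalescenceResult:
    """Pair-identity probabilities and the derived diversities.

    F_f / F_b are the probabilities that two focal-locus / background
    copies sampled at t_end are identical; D = 1/F; DR = D_bg / D_f.
    """

    F_f: float
    F_b: float
    D_f: float
    D_bg: float
    DR: float
    C_end: float


def _check_kind(locus_kind: str) -> str:
    if locus_kind not in ("focal", "background"):
        raise ValueError(f"locus_kind must be 'focal' or 'background', got {locus_kind!r}")
    return locus_kind


def sample_pair(C_end: float, locus_kind: str = "background") -> PairStateDist:
    """Distribution of a random pair of cells at the sampling time."""
    if not 0.0 <= C_end <= 1.0:
        raise ValueError(f"carrier fraction outside [0, 1]: {C_end}")
    _check_kind(locus_kind)
    p = np.zeros(6)
    p[_S11] = C_end**2
    p[_S01] = 2.0 * C_end * (1.0 - C_end)
    p[_S00] = (1.0 - C_end) ** 2
    return PairStateDist(p, locus_kind)


def backward_rates(C: float, p: SweepParams, locus_kind: str) -> np.ndarray:
    """6x6 backward transition-rate table Q (rows: from-state; per generation).

    Row sums are zero (diagonal balances the off-diagonal rates), so the
    master equation conserves probability.  Class frequencies in rate
    denominators are floored at 1/N: an occupied class holds at least one
    cell, and states whose occupancy truly vanishes carry no mass.
    """
    _check_kind(locus_kind)
    N = float(p.N)
    Cc = max(C, 1.0 / N)
    Uc = max(1.0 - C, 1.0 / N)
    Q = np.zeros((6, 6))

    Q[_S11, _S1] = 1.0 / (N * Cc)
    Q[_S00, _S0] = 1.0 / (N * Uc)
    if p.m > 0:
        Q[_S00, _SM] = 2.0 * p.m / Uc
        Q[_S01, _SM] = p.m / Uc
    if locus_kind == "background":
        Q[_S11, _S01] = 2.0 * p.r * (1.0 - C)
        Q[_S01, _S00] = p.r * (1.0 - C)
    else:  # focal: donor jump may land on the partner lineage's carrier
        Q[_S11, _S1] += 2.0 * p.r * (1.0 - C) / (N * Cc)
    Q[np.diag_indices(6)] = -Q.sum(axis=1)
    return Q


def solve_pair(
    p: SweepParams,
    t_end: float,
    locus_kind: str,
    trajectory: Trajectory | None = None,
) -> PairStateDist:
    """Integrate the backward master equation from sampling back to t = 0.

    The forward carrier dynamics are computed (or supplied) first; the
    six-state master equation dP/dtau = Q(C(t_end - tau))^T P is then
    integrated over backward time tau in [0, t_end] starting from the
    random-pair distribution at C(t_end).
    """
    _check_kind(locus_kind)
    traj = trajectory if trajectory is not None else integrate(p, t_end)
    dense = traj.dense
    if dense is None:
        raise ValueError("trajectory must carry a dense forward solution")

    C_end = float(np.clip(dense(t_end)[0], 0.0, 1.0))
    y0 = sample_pair(C_end, locus_kind).probabilities

    def rhs(tau: float, y: np.ndarray) -> np.ndarray:
        C = float(np.clip(dense(t_end - tau)[0], 0.0, 1.0))
        return backward_rates(C, p, locus_kind).T @ y

    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-14,
    )
    if not sol.success:
        raise IntegrationError(f"backward solver failed: {sol.message}")
    y = sol.y[:, -1]
    if abs(y.sum() - 1.0) > CONS_TOL:
        raise IntegrationError(
            f"probability not conserved: sum = {y.sum():.12f}"
        )
    y = np.clip(y, 0.0, None)
    y = y / y.sum()
    return PairStateDist(y, locus_kind)


def diversity_ratio(
    p: SweepParams,
    t_end: float,
    trajectory: Trajectory | None = None,
) -> CoalescenceResult:
    """Focal and background diversities and their ratio DR = D_bg / D_f.

    Identity probability per locus kind: F = P(S1) + P(S0) + P(S11) at
    t = 0 (coalesced, or both lineages in the single founding carrier
    clone).  D = 1/F mirrors the order-2 Hill number used by the
    individual-based model.
    """
    traj = trajectory if trajectory is not None else integrate(p, t_end)

    def identity(kind: str) -> float:
        dist = solve_pair(p, t_end, kind, trajectory=traj)
        return dist["S1"] + dist["S0"] + dist["S11"]

    F_f = identity("focal")
    F_b = identity("background")
    if F_f <= 0.0 or F_b <= 0.0:
        raise IntegrationError(
            f"identity probability at numerical floor: F_f={F_f}, F_b={F_b}"
        )
    C_end = float(np.clip(traj.dense(t_end)[0], 0.0, 1.0))
    return CoalescenceResult(
        F_f=F_f,
        F_b=F_b,
        D_f=1.0 / F_f,
        D_bg=1.0 / F_b,
        DR=F_f / F_b,
        C_end=C_end,
    )
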