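"""Individual-based Wright-Fisher model with resource niches.

A community of exactly ``N`` cells evolves in discrete generations.  Each
cell is a triple (focal allele, background genotype, niche): the focal
locus is transferrable (state 1 = adapted, any other positive integer = a
non-adapted variant), the background genotype is a non-transferrable
positive-integer label, and the niche index assigns the cell to one of
``n`` resource niches.

Each generation:

1. *resources* -- every niche holds a share N/n; a cell of fitness f
   (1+s for carriers, 1 otherwise) competes in its own niche with weight
   f*z and in each other niche with weight f*(1-z)/(n-1); it harvests
   from each niche proportionally to its relative competitive weight
   there (empty niches forfeit their share).
2. *reproduction* -- the harvested resources R_i are the mean offspring
   number; offspring counts are independent Poissons conditioned on the
   fixed total N, i.e. a multinomial over cell classes with weights
   count_i * R_i.
3. *transfer* -- every non-carrier acquires the focal allele with
   probability C*r, keeping its background genome and niche.
4. *migration* -- Binomial(N, m) uniformly chosen cells are replaced by
   immigrants; each immigrant lacks the focal allele, carries a globally
   unique genotype and lands in a uniformly random niche.

State representation
--------------------
Counts are kept over distinct (focal, background, niche) classes rather
than per-cell arrays.  Genotypes whose integer label is never shared with
any other class -- initial non-carriers and immigrants -- are furthermore
*anonymous*: they are exchangeable, so instead of one row per lineage the
state keeps occupancy buckets ``bucket[q, c]`` = number of anonymous
non-carrier lineages of copy number ``c`` in niche ``q``.  Their
reproduction, thinning by migration and conversion by transfer are
sampled with vectorized occupancy draws that realize exactly the same
laws as per-lineage sampling (multinomial aggregation within equal-weight
groups; block mapping of uniformly chosen distinct cells onto lineages).
A lineage leaves the bucket only when its label starts to matter -- when
horizontal transfer copies the focal allele into some of its cells -- at
which point it is promoted to explicit rows with a fresh identifier.
This keeps the explicit table small even though migration injects
``m*N`` unique genotypes per generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import hill2

__all__ = [
    "IBMParams",
    "CommunityState",
    "ResourceTable",
    "SimulationError",
    "init_community",
    "niche_weights",
    "allocate_resources",
    "reproduce",
    "transfer_step",
    "migrate_step",
    "community_metrics",
    "run",
]


class SimulationError(RuntimeError):
    """The stochastic update could not proceed (e.g. no resources at all)."""


@dataclass(frozen=True)
class IBMParams:
    """Parameters of the niche-structured individual-based model."""

    N: int
    s: float = 0.0
    r: float = 0.0
    m: float = 0.0
    C0: float = 0.0
    n: int = 1
    z: float = 1.0
    t_end: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError(f"z must lie in [0, 1], got {self.z}")
        if self.n > 1 and self.z < 1.0 / self.n:
            warnings.warn(
                f"z={self.z} < 1/n={1.0 / self.n:.3f}: cells compete more in "
                "foreign niches than their own",
                stacklevel=2,
            )
        for name in ("r", "m", "C0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.s < 0.0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        if self.t_end < 0:
            raise ValueError(f"t_end must be >= 0, got {self.t_end}")


@dataclass
class CommunityState:
    """Cell classes: explicit (focal, background, niche) rows plus buckets.

    ``bucket[q, c]`` counts anonymous unique non-carrier genotypes with
    exactly ``c`` cells in niche ``q`` (column 0 is unused).  Explicit rows
    hold every class whose genotype label is shared or carries the focal
    allele.
    """

    focal: np.ndarray
    background: np.ndarray
    niche: np.ndarray
    count: np.ndarray
    bucket: np.ndarray
    next_id: int
    generation: int = 0
    _groups: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def bucket_cells_per_niche(self) -> np.ndarray:
        return self.bucket @ np.arange(self.bucket.shape[1], dtype=np.int64)

    @property
    def N(self) -> int:
        return int(self.count.sum() + self.bucket_cells_per_niche.sum())

    @property
    def carrier_mask(self) -> np.ndarray:
        return self.focal == 1

    @property
    def carriers(self) -> int:
        return int(self.count[self.carrier_mask].sum())

    @property
    def carrier_fraction(self) -> float:
        n = self.N
        return self.carriers / n if n else 0.0

    def compact(self) -> "CommunityState":
        """Drop zero-count explicit classes (in place) and return self."""
        keep = self.count > 0
        if not keep.all():
            self.focal = self.focal[keep]
            self.background = self.background[keep]
            self.niche = self.niche[keep]
            self.count = self.count[keep]
        return self

    def _bucket_groups(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Occupied bucket groups as (niche q, copy number c, #lineages j).

        Cached; any mutation of ``bucket`` must call ``_dirty()``.
        """
        if self._groups is None:
            q, c = np.nonzero(self.bucket[:, 1:])
            c = (c + 1).astype(np.int64)
            self._groups = (q.astype(np.int64), c, self.bucket[q, c].astype(np.int64))
        return self._groups

    def _dirty(self) -> None:
        self._groups = None

    def bucket_lineage_counts(self) -> np.ndarray:
        """Copy numbers of all anonymous lineages, one entry per lineage."""
        q, c, j = self._bucket_groups()
        return np.repeat(c, j)


@dataclass
class ResourceTable:
    """Per-class fitness, competitive weights and harvested resources.

    ``R_i`` is the per-cell resource total (mean offspring number) of each
    explicit class, ``R_bucket[q]`` that of an anonymous non-carrier in
    niche ``q``, and ``Omega[j]`` the summed competitive weight in niche
    ``j``.  The dense per-niche tables (sigma_ij, omega_ij, R_ij over the
    explicit classes) are materialized on demand for inspection and
    testing; the simulation loop only needs R_i and R_bucket.
    """

    f: np.ndarray
    Omega: np.ndarray
    R_i: np.ndarray
    R_bucket: np.ndarray
    _niche: np.ndarray = field(repr=False)
    _n: int = field(repr=False)
    _z: float = field(repr=False)
    _N: int = field(repr=False)

    @property
    def sigma_ij(self) -> np.ndarray:
        k = len(self.f)
        off = 0.0 if self._n == 1 else (1.0 - self._z) / (self._n - 1)
        own = 1.0 if self._n == 1 else self._z
        sig = np.full((k, self._n), off)
        sig[np.arange(k), self._niche] = own
        return sig

    @property
    def omega_ij(self) -> np.ndarray:
        return self.f[:, None] * self.sigma_ij

    @property
    def R_ij(self) -> np.ndarray:
        share = self._N / self._n
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.Omega > 0, self.omega_ij / self.Omega * share, 0.0)


def niche_weights(p: IBMParams, niche: int = 0) -> np.ndarray:
    """Niche-association row sigma for a cell assigned to ``niche``.

    sigma = z for the assigned niche and (1-z)/(n-1) for every other
    niche (sigma = 1 when n = 1, regardless of z); rows sum to 1.
    """
    if p.n == 1:
        return np.array([1.0])
    sig = np.full(p.n, (1.0 - p.z) / (p.n - 1))
    sig[niche] = p.z
    return sig


def init_community(p: IBMParams, rng: np.random.Generator | None = None) -> CommunityState:
    """Initial community: one founding carrier clone plus unique non-carriers.

    round(C0*N) cells form a single carrier clone (focal = background = 1);
    every remaining cell is its own unique genotype with matching focal and
    background labels.  Niches are assigned uniformly at random.
    """
    rng = np.random.default_rng(p.seed) if rng is None else rng
    nc = int(round(p.C0 * p.N))
    if p.C0 > 0 and nc == 0:
        warnings.warn(
            f"C0={p.C0} rounds to zero carriers at N={p.N}; the sweep cannot start",
            stacklevel=2,
        )
    uniform = np.full(p.n, 1.0 / p.n)
    clone_per_niche = rng.multinomial(nc, uniform) if nc > 0 else np.zeros(p.n, np.int64)
    qs = np.flatnonzero(clone_per_niche).astype(np.int64)
    bucket = np.zeros((p.n, 2), dtype=np.int64)
    bucket[:, 1] = rng.multinomial(p.N - nc, uniform)
    return CommunityState(
        focal=np.ones(len(qs), dtype=np.int64),
        background=np.ones(len(qs), dtype=np.int64),
        niche=qs,
        count=clone_per_niche[qs].astype(np.int64),
        bucket=bucket,
        next_id=2,
    )


def allocate_resources(state: CommunityState, p: IBMParams) -> ResourceTable:
    """Harvest the N/n resource share of every niche across cell classes.

    R_ij = (omega_ij / Omega_j) * N/n and R_i = sum_j R_ij; empty niches
    (Omega_j = 0) distribute nothing.
    """
    f = np.where(state.carrier_mask, 1.0 + p.s, 1.0)
    w = state.count * f
    share = p.N / p.n
    bpn = state.bucket_cells_per_niche.astype(float)  # anonymous cells have f=1
    if p.n == 1:
        Omega = np.array([w.sum() + bpn[0]])
        inv0 = share / Omega[0] if Omega[0] > 0 else 0.0
        R = f * inv0
        R_bucket = np.array([inv0])
    else:
        off = (1.0 - p.z) / (p.n - 1)
        Wj = np.bincount(state.niche, weights=w, minlength=p.n) + bpn
        Omega = off * (Wj.sum() - Wj) + p.z * Wj
        inv = np.where(Omega > 0, 1.0 / np.where(Omega > 0, Omega, 1.0), 0.0)
        common = off * inv.sum()
        per_niche = share * (common + (p.z - off) * inv)
        R = f * per_niche[state.niche]
        R_bucket = per_niche
    return ResourceTable(
        f=f, Omega=Omega, R_i=R, R_bucket=R_bucket,
        _niche=state.niche, _n=p.n, _z=p.z, _N=p.N,
    )


def reproduce(
    state: CommunityState,
    resources: ResourceTable,
    rng: np.random.Generator,
    p: IBMParams,
) -> CommunityState:
    """Wright-Fisher update: multinomial offspring with weights count_i * R_i.

    This is the law of independent Poisson(R_i) offspring per cell
    conditioned on the total staying exactly N; offspring inherit all
    three numbers.  Anonymous lineages are resampled through their
    occupancy buckets: a group of j equal-weight lineages first receives
    its multinomial total, which is then dropped uniformly onto the j
    lineages (multinomial aggregation, exact).
    """
    q_g, c_g, j_g = state._bucket_groups()
    w = np.concatenate([state.count * resources.R_i, j_g * c_g * resources.R_bucket[q_g]])
    tot = w.sum()
    if tot <= 0:
        raise SimulationError("no class obtained any resources")
    T = rng.multinomial(p.N, w / tot)
    k = len(state.count)
    state.count = T[:k].astype(np.int64)

    T_g = T[k:]
    n_lin = int(j_g.sum())
    if n_lin > 0:
        jrep = np.repeat(j_g, T_g)
        starts = np.concatenate([[0], np.cumsum(j_g)[:-1]]) if len(j_g) else np.empty(0, np.int64)
        base = np.repeat(starts, T_g)
        idx = base + np.minimum((rng.random(int(T_g.sum())) * jrep).astype(np.int64), jrep - 1)
        occ = np.bincount(idx, minlength=n_lin)
        vmax = int(occ.max()) if occ.size else 0
        width = max(vmax + 1, 2)
        niche_per_lin = np.repeat(q_g, j_g)
        alive = occ > 0
        key = niche_per_lin[alive] * width + occ[alive]
        state.bucket = (
            np.bincount(key, minlength=p.n * width).reshape(p.n, width).astype(np.int64)
        )
    else:
        state.bucket = np.zeros((p.n, 2), dtype=np.int64)
    state._dirty()
    state.generation += 1
    return state.compact()


def _dedup(a: np.ndarray) -> np.ndarray:
    """Sorted distinct values of a (sort-based; faster than np.unique here)."""
    s = np.sort(a)
    if s.size < 2:
        return s
    return s[np.concatenate(([True], s[1:] != s[:-1]))]


def _value_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distinct values of a and their multiplicities."""
    s = np.sort(a)
    edge = np.flatnonzero(np.concatenate(([True], s[1:] != s[:-1])))
    return s[edge], np.diff(np.concatenate((edge, [s.size])))


def _distinct_cells(rng: np.random.Generator, n_total: int, k: int) -> np.ndarray:
    """k distinct uniform cell positions in [0, n_total), sorted."""
    if k >= n_total:
        return np.arange(n_total, dtype=np.int64)
    if k > n_total // 2:  # sample the complement instead
        keep = _distinct_cells(rng, n_total, n_total - k)
        mask = np.ones(n_total, dtype=bool)
        mask[keep] = False
        return np.flatnonzero(mask).astype(np.int64)
    out = _dedup(rng.integers(0, n_total, size=k, dtype=np.int64))
    while out.size < k:
        extra = rng.integers(0, n_total, size=k - out.size, dtype=np.int64)
        out = _dedup(np.concatenate([out, extra]))
    return out


def _promote(
    state: CommunityState, q: int, c: int, converted: int
) -> None:
    """Promote one anonymous lineage hit by transfer to explicit rows."""
    state.bucket[q, c] -= 1
    state._dirty()
    gid = state.next_id
    state.next_id += 1
    new_focal = [1]
    new_bg = [gid]
    new_niche = [q]
    new_count = [converted]
    if c - converted > 0:
        new_focal.append(gid)
        new_bg.append(gid)
        new_niche.append(q)
        new_count.append(c - converted)
    state.focal = np.concatenate([state.focal, np.asarray(new_focal, np.int64)])
    state.background = np.concatenate([state.background, np.asarray(new_bg, np.int64)])
    state.niche = np.concatenate([state.niche, np.asarray(new_niche, np.int64)])
    state.count = np.concatenate([state.count, np.asarray(new_count, np.int64)])


def transfer_step(
    state: CommunityState, rng: np.random.Generator, p: IBMParams
) -> tuple[CommunityState, int]:
    """Horizontal transfer: each non-carrier gains the allele w.p. C*r.

    Converted cells keep background genome and niche; returns the state
    and the realized number of conversions (this generation's realized
    gene flux).  A converted anonymous lineage is promoted to explicit
    rows (carrier part and unconverted remnant share a fresh genotype
    label).
    """
    C = state.carrier_fraction
    if p.r == 0.0 or C == 0.0 or C == 1.0:
        return state, 0
    pc = C * p.r
    total = 0

    nonc = ~state.carrier_mask
    conv = rng.binomial(state.count[nonc], pc)
    if conv.sum() > 0:
        idx = np.flatnonzero(nonc)
        src = idx[conv > 0]
        moved = conv[conv > 0].astype(np.int64)
        total += int(moved.sum())
        state.count[src] -= moved
        state.focal = np.concatenate([state.focal, np.ones(len(src), np.int64)])
        state.background = np.concatenate([state.background, state.background[src]])
        state.niche = np.concatenate([state.niche, state.niche[src]])
        state.count = np.concatenate([state.count, moved])

    q_g, c_g, j_g = state._bucket_groups()
    cells_g = j_g * c_g
    n_cells = int(cells_g.sum())
    if n_cells > 0:
        K = int(rng.binomial(n_cells, pc))
        if K > 0:
            pos = _distinct_cells(rng, n_cells, K)
            ends = np.cumsum(cells_g)
            grp = np.searchsorted(ends, pos, side="right")
            off = pos - (ends[grp] - cells_g[grp])
            lin = off // c_g[grp]
            keys, hits = _value_counts(grp * (n_cells + 1) + lin)
            for key, h in zip(keys, hits):
                g = int(key // (n_cells + 1))
                _promote(state, int(q_g[g]), int(c_g[g]), int(h))
            total += K
    return state.compact(), total


def migrate_step(
    state: CommunityState, rng: np.random.Generator, p: IBMParams
) -> CommunityState:
    """Replace Binomial(N, m) uniformly chosen cells by unique immigrants.

    Immigrants lack the focal allele, are globally unique genotypes and
    land in uniformly random niches; uniform thinning removes carriers at
    expected rate m*C per generation, matching the compartment model's
    -m*C term.  Immigrants join the anonymous buckets directly.
    """
    if p.m == 0.0:
        return state
    M = int(rng.binomial(p.N, p.m))
    if M == 0:
        return state
    pos = _distinct_cells(rng, p.N, M)

    n_explicit = int(state.count.sum())
    in_explicit = pos < n_explicit
    if in_explicit.any():
        ends = np.cumsum(state.count)
        rows = np.searchsorted(ends, pos[in_explicit], side="right")
        np.subtract.at(state.count, rows, 1)

    bpos = pos[~in_explicit] - n_explicit
    if bpos.size:
        q_g, c_g, j_g = state._bucket_groups()
        cells_g = j_g * c_g
        ends = np.cumsum(cells_g)
        grp = np.searchsorted(ends, bpos, side="right")
        off = bpos - (ends[grp] - cells_g[grp])
        lin = off // c_g[grp]
        keys, hits = _value_counts(grp * (int(cells_g.sum()) + 1) + lin)
        g_idx = (keys // (int(cells_g.sum()) + 1)).astype(np.int64)
        old_c = c_g[g_idx]
        new_c = old_c - hits
        np.add.at(state.bucket, (q_g[g_idx], old_c), -1)
        survivors = new_c > 0
        if survivors.any():
            np.add.at(state.bucket, (q_g[g_idx][survivors], new_c[survivors]), 1)

    state.bucket[:, 1] += rng.multinomial(M, np.full(p.n, 1.0 / p.n))
    state._dirty()
    return state.compact()


def community_metrics(state: CommunityState) -> tuple[float, float, float]:
    """(D_f, D_bg, DR): order-2 Hill diversities of both loci and their ratio."""
    blc = state.bucket_lineage_counts()
    carrier = state.carrier_mask
    carriers = state.count[carrier].sum()
    focal_counts = np.concatenate(
        [[carriers] if carriers > 0 else [], state.count[~carrier], blc]
    )
    d_f = hill2(focal_counts)
    _, inv = np.unique(state.background, return_inverse=True)
    bg_counts = np.concatenate([np.bincount(inv, weights=state.count), blc])
    d_bg = hill2(bg_counts)
    return d_f, d_bg, d_bg / d_f


def run(p: IBMParams, metrics_every: int = 1) -> pd.DataFrame:
    """Simulate ``t_end`` generations and record the per-generation series.

    Each generation applies resources -> reproduction -> transfer ->
    migration, recording the carrier fraction and realized gene flux
    every generation and the diversities D_f, D_bg, DR every
    ``metrics_every`` generations (always at generation 0 and t_end;
    other rows hold NaN).  Output is bit-for-bit reproducible given
    (params, seed).
    """
    if metrics_every < 1:
        raise ValueError("metrics_every must be >= 1")
    rng = np.random.default_rng(p.seed)
    state = init_community(p, rng)

    C = np.empty(p.t_end + 1)
    flux = np.zeros(p.t_end + 1)
    D_f = np.full(p.t_end + 1, np.nan)
    D_bg = np.full(p.t_end + 1, np.nan)

    C[0] = state.carrier_fraction
    D_f[0], D_bg[0], _ = community_metrics(state)
    for t in range(1, p.t_end + 1):
        resources = allocate_resources(state, p)
        state = reproduce(state, resources, rng, p)
        state, conversions = transfer_step(state, rng, p)
        state = migrate_step(state, rng, p)
        if state.N != p.N:
            raise SimulationError(
                f"community size drifted to {state.N} != {p.N} at generation {t}"
            )
        C[t] = state.carrier_fraction
        flux[t] = conversions
        if t % metrics_every == 0 or t == p.t_end:
            D_f[t], D_bg[t], _ = community_metrics(state)

    with np.errstate(invalid="ignore"):
        DR = D_bg / D_f
    return pd.DataFrame(
        {
            "generation": np.arange(p.t_end + 1),
            "C": C,
            "flux_realized": flux,
            "D_f": D_f,
            "D_bg": D_bg,
            "DR": DR,
        }
    )
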