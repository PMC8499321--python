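"""Individual-based simulation of a *Pantoea* population on a nutrient grid.

The world is a bounded (non-wrapping) square lattice of patches representing
a thin layer of R2A-like medium, 605 μm on a side and 10-50 μm deep.  Each
patch holds glucose-carbon and ammonium-nitrogen mass; each bacterium is an
agent with its own biomass-carbon, age since last division, starvation clock
and patch coordinate.  One tick of ``steptime`` minutes applies, in order:

1. nutrient redistribution — every patch passes a fraction ``D`` of each
   nutrient to its 8-neighbourhood (edge patches retain undistributed
   shares, so mass is conserved exactly);
2. metabolism — Monod-limited glucose uptake (half-saturation ``K_S``),
   maintenance deducted first, the post-maintenance carbon split into
   biomass (fraction ``efficiency``) and respired CO₂, with growth
   re-limited by patch ammonium through the C_4.17 H_8 O_1.75 N biomass
   stoichiometry; cells whose uptake cannot cover maintenance accumulate
   starvation time and die once it exceeds ``max_time_viability_pa``;
3. bipartition — a cell divides once it has doubled its birth mass and is at
   least ``rep_pa`` minutes past its last division, subject to the per-patch
   capacity ``pmax`` (daughters spill into a random non-full neighbour;
   division is deferred when all are full).

Carbon and nitrogen ledgers (live biomass, dead biomass, respired carbon,
nutrient fields) are closed to floating-point accuracy throughout a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numba
import numpy as np

from .config import ParameterSet, validate_parameters
from .growth import PopulationCurve

__all__ = [
    "STOICHIOMETRY",
    "Stoichiometry",
    "Bacterium",
    "WorldState",
    "spherocylinder_volume_um3",
    "sample_cell_dimensions",
    "new_cell_mass",
    "monod_uptake",
    "diffuse_field",
    "initialize_world",
    "step",
    "run",
]

# atomic masses, g/mol
_M_C, _M_H, _M_O, _M_N = 12.011, 1.008, 15.999, 14.007

#: assumed wet cell density, g/cm^3
CELL_DENSITY_G_PER_CM3 = 1.1
#: dry mass : wet mass ratio used to convert density-derived wet mass to dry biomass
DEFAULT_DRY_FRACTION = 0.3
#: Monod half-saturation constant for glucose, mM
DEFAULT_KS_MM = 0.5
#: lattice resolution, μm per patch side
DEFAULT_PATCH_SIDE_UM = 5.0
#: mean±SD cell length and width, μm
CELL_LENGTH_UM = (1.1, 0.5)
CELL_WIDTH_UM = (0.55, 0.25)


@dataclass(frozen=True)
class Stoichiometry:
    """Elemental composition of biomass (C4.17 H8 O1.75 N) and nutrients.

    Derived quantities are recomputed from atomic masses rather than
    hard-coded.
    """

    formula_C: float = 4.17
    formula_H: float = 8.0
    formula_O: float = 1.75
    formula_N: float = 1.0

    @property
    def formula_mass(self) -> float:
        return (
            self.formula_C * _M_C
            + self.formula_H * _M_H
            + self.formula_O * _M_O
            + self.formula_N * _M_N
        )

    @property
    def carbon_mass_fraction(self) -> float:
        """gC per g dry biomass."""
        return self.formula_C * _M_C / self.formula_mass

    @property
    def N_per_C(self) -> float:
        """gN bound in biomass per gC of biomass."""
        return self.formula_N * _M_N / (self.formula_C * _M_C)

    @property
    def glucose_C_per_mol(self) -> float:
        """g of carbon per mol glucose (C6H12O6)."""
        return 6.0 * _M_C

    @property
    def ammonium_N_per_mol(self) -> float:
        """g of nitrogen per mol ammonium."""
        return _M_N


STOICHIOMETRY = Stoichiometry()


@dataclass
class Bacterium:
    """Read-only view of one agent (the engine stores agents in arrays)."""

    id: int
    biomass_C: float
    birth_mass_C: float
    age_since_division: float
    starvation_time: float
    patch_index: tuple[int, int]
    alive: bool = True


def spherocylinder_volume_um3(length_um, width_um):
    """Volume of a rod of total length L and diameter W (cylinder + caps)."""
    r = np.asarray(width_um) / 2.0
    L = np.asarray(length_um)
    return np.pi * r**2 * (L - np.asarray(width_um)) + (4.0 / 3.0) * np.pi * r**3


def sample_cell_dimensions(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (length, width) pairs in μm, truncated so that L >= W > 0."""
    L = np.empty(n)
    W = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        lt = rng.normal(CELL_LENGTH_UM[0], CELL_LENGTH_UM[1], todo.size)
        wt = rng.normal(CELL_WIDTH_UM[0], CELL_WIDTH_UM[1], todo.size)
        ok = (wt > 0) & (lt >= wt)
        L[todo[ok]] = lt[ok]
        W[todo[ok]] = wt[ok]
        todo = todo[~ok]
    return L, W


def new_cell_mass(
    rng: np.random.Generator,
    n: int | None = None,
    dry_fraction: float = DEFAULT_DRY_FRACTION,
) -> float | np.ndarray:
    """Draw initial biomass-carbon (g) from the cell-geometry model.

    Cell shape is a spherocylinder with normally distributed length and
    width; wet mass follows from a density of 1.1 g/cm^3, converted to
    carbon via the dry fraction and the biomass carbon mass fraction.
    """
    scalar = n is None
    m = 1 if scalar else n
    L, W = sample_cell_dimensions(rng, m)
    vol_cm3 = spherocylinder_volume_um3(L, W) * 1e-12  # 1 μm^3 = 1e-12 cm^3
    wet = vol_cm3 * CELL_DENSITY_G_PER_CM3
    biomass_C = wet * dry_fraction * STOICHIOMETRY.carbon_mass_fraction
    return float(biomass_C[0]) if scalar else biomass_C


def monod_uptake(
    S_patch_mM: float,
    umax: float,
    biomass_C: float,
    dt_min: float,
    ks_mM: float = DEFAULT_KS_MM,
    efficiency: float = 0.37,
) -> float:
    """Glucose-carbon demanded by one cell over one tick (g, uncapped).

    Demand = (umax/60)·dt · S/(K_S+S) · biomass_C / efficiency: the Monod
    growth demand divided by the yield so that gross uptake covers both new
    biomass and the respired share.  Availability capping (proportional
    sharing on a patch) is applied by the engine, not here.
    """
    if min(S_patch_mM, umax, biomass_C, dt_min) < 0:
        raise ValueError("monod_uptake arguments must be non-negative")
    monod = S_patch_mM / (ks_mM + S_patch_mM) if S_patch_mM > 0 else 0.0
    return (umax / 60.0) * dt_min * monod * biomass_C / efficiency


@numba.njit(cache=False)
def _diffuse_kernel(field, D):  # pragma: no cover - exercised via diffuse_field
    n, m = field.shape
    out = np.empty((n, m))
    d8 = D / 8.0
    for i in range(n):
        for j in range(m):
            s = 0.0
            k = 0
            for di in range(-1, 2):
                ii = i + di
                if ii < 0 or ii >= n:
                    continue
                for dj in range(-1, 2):
                    jj = j + dj
                    if jj < 0 or jj >= m or (di == 0 and dj == 0):
                        continue
                    s += field[ii, jj]
                    k += 1
            out[i, j] = field[i, j] - d8 * k * field[i, j] + d8 * s
    return out


def diffuse_field(field: np.ndarray, D: float) -> np.ndarray:
    """One redistribution step: each patch keeps (1-D) of its mass and sends
    D/8 to each *existing* neighbour; shares toward missing neighbours (grid
    edge) are retained, so total mass is conserved exactly."""
    if not (0.0 <= D <= 1.0):
        raise ValueError(f"diffusion fraction D={D} outside [0, 1]")
    if np.any(field < 0):
        raise ValueError("nutrient field must be non-negative")
    if D == 0.0:
        return field.copy()
    return _diffuse_kernel(np.ascontiguousarray(field, dtype=np.float64), D)


@lru_cache(maxsize=8)
def _neighbor_counts(n: int, m: int) -> np.ndarray:
    ones = np.ones((n, m))
    padded = np.zeros((n + 2, m + 2))
    padded[1:-1, 1:-1] = ones
    return (
        padded[:-2, :-2] + padded[:-2, 1:-1] + padded[:-2, 2:]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        + padded[2:, :-2] + padded[2:, 1:-1] + padded[2:, 2:]
    )


def _neighbor_table(side: int) -> np.ndarray:
    """(side*side, 8) flat indices of the 8-neighbourhood, -1 where absent."""
    idx = np.arange(side * side).reshape(side, side)
    table = np.full((side * side, 8), -1, dtype=np.int64)
    k = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            src = np.full((side, side), -1, dtype=np.int64)
            r0, r1 = max(dr, 0), side + min(dr, 0)
            c0, c1 = max(dc, 0), side + min(dc, 0)
            src[r0:r1, c0:c1] = idx[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            table[:, k] = src.ravel()
            k += 1
    return table


@dataclass
class WorldState:
    """Full simulation state: nutrient grids, agent arrays and mass ledgers."""

    params: ParameterSet
    grid_side: int
    patch_side_um: float
    depth_um: float
    glucose_C: np.ndarray
    ammonium_N: np.ndarray
    rng: np.random.Generator
    ks_mM: float = DEFAULT_KS_MM
    dry_fraction: float = DEFAULT_DRY_FRACTION
    respired_C: float = 0.0
    dead_biomass_C: float = 0.0
    tick: int = 0
    # agent arrays (parallel, live cells only)
    biomass: np.ndarray = field(default_factory=lambda: np.empty(0))
    birth_mass: np.ndarray = field(default_factory=lambda: np.empty(0))
    age_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    starv_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    patch: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    next_id: int = 0

    def __post_init__(self):
        self._nbr_table = _neighbor_table(self.grid_side)

    # ---- conversions -------------------------------------------------
    @property
    def patch_volume_L(self) -> float:
        return self.patch_side_um**2 * self.depth_um * 1e-15

    @property
    def glucose_gC_per_mM(self) -> float:
        """g of glucose-carbon in one patch per mM of concentration."""
        return 1e-3 * self.patch_volume_L * STOICHIOMETRY.glucose_C_per_mol

    @property
    def ammonium_gN_per_mM(self) -> float:
        return 1e-3 * self.patch_volume_L * STOICHIOMETRY.ammonium_N_per_mol

    # ---- bookkeeping -------------------------------------------------
    @property
    def n_alive(self) -> int:
        return self.biomass.size

    def live_biomass_C(self) -> float:
        return float(self.biomass.sum())

    def carbon_total(self) -> float:
        return (
            float(self.glucose_C.sum())
            + self.live_biomass_C()
            + self.dead_biomass_C
            + self.respired_C
        )

    def nitrogen_total(self) -> float:
        bound = STOICHIOMETRY.N_per_C * (self.live_biomass_C() + self.dead_biomass_C)
        return float(self.ammonium_N.sum()) + bound

    def patch_counts(self) -> np.ndarray:
        return np.bincount(self.patch, minlength=self.grid_side**2)

    def count_grid(self) -> np.ndarray:
        return self.patch_counts().reshape(self.grid_side, self.grid_side)

    def bacteria(self) -> list[Bacterium]:
        g = self.grid_side
        return [
            Bacterium(
                id=int(self.ids[i]),
                biomass_C=float(self.biomass[i]),
                birth_mass_C=float(self.birth_mass[i]),
                age_since_division=float(self.age_min[i]),
                starvation_time=float(self.starv_min[i]),
                patch_index=(int(self.patch[i]) // g, int(self.patch[i]) % g),
            )
            for i in range(self.n_alive)
        ]


def initialize_world(
    p: ParameterSet,
    seed: int,
    patch_side_um: float = DEFAULT_PATCH_SIDE_UM,
    ks_mM: float = DEFAULT_KS_MM,
    dry_fraction: float = DEFAULT_DRY_FRACTION,
) -> WorldState:
    """Create the tick-0 world: uniform nutrient fields and randomly placed
    founder cells (at most ``pmax`` per patch)."""
    validate_parameters(p)
    side = math.ceil(p.total_length_world / patch_side_um)
    rng = np.random.default_rng(seed)
    world = WorldState(
        params=p,
        grid_side=side,
        patch_side_um=patch_side_um,
        depth_um=p.depth,
        glucose_C=np.empty((side, side)),
        ammonium_N=np.empty((side, side)),
        rng=rng,
        ks_mM=ks_mM,
        dry_fraction=dry_fraction,
    )
    world.glucose_C[:] = p.glucose * world.glucose_gC_per_mM
    world.ammonium_N[:] = p.ammonium * world.ammonium_gN_per_mM

    n0 = int(p.microorganism)
    n_patches = side * side
    if n0 > p.pmax * n_patches:
        raise ValueError(
            f"cannot place {n0} cells: capacity is pmax*patches = {p.pmax * n_patches}"
        )
    counts = np.zeros(n_patches, dtype=np.int64)
    placed = np.empty(n0, dtype=np.int64)
    k = 0
    while k < n0:
        cand = rng.integers(n_patches, size=n0 - k)
        for q in cand:
            if counts[q] < p.pmax:
                counts[q] += 1
                placed[k] = q
                k += 1
                if k == n0:
                    break
    world.patch = placed
    world.biomass = new_cell_mass(rng, n0, dry_fraction)
    world.birth_mass = world.biomass.copy()
    world.age_min = np.zeros(n0)
    world.starv_min = np.zeros(n0)
    world.ids = np.arange(n0, dtype=np.int64)
    world.next_id = n0
    return world


@numba.njit(cache=False)
def _metabolize_kernel(
    patch, biomass, starv, glc, amm,
    gC_per_mM, ks, umax, dt, eff, maint, n_per_C,
):  # pragma: no cover - exercised through _metabolize_all
    n = biomass.size
    n_patch = glc.size
    demand = np.empty(n)
    patch_demand = np.zeros(n_patch)
    coef = (umax / 60.0) * dt / eff
    for i in range(n):
        q = patch[i]
        S = glc[q] / gC_per_mM
        monod = S / (ks + S) if S > 0.0 else 0.0
        d = coef * monod * biomass[i]
        demand[i] = d
        patch_demand[q] += d

    # proportional sharing when a patch is over-demanded
    share = np.empty(n_patch)
    for q in range(n_patch):
        if patch_demand[q] > glc[q] and patch_demand[q] > 0.0:
            share[q] = glc[q] / patch_demand[q]
        else:
            share[q] = 1.0

    grow = np.empty(n, np.bool_)
    dC = np.empty(n)
    patch_n_need = np.zeros(n_patch)
    mcoef = maint * (dt / 60.0)
    for i in range(n):
        q = patch[i]
        U = demand[i] * share[q]
        demand[i] = U  # reuse as realized uptake
        M = mcoef * biomass[i]
        # relative epsilon so a last-ulp rounding of a shared uptake cannot
        # flip the exact U == M boundary into the starvation branch
        g = U >= M * (1.0 - 1e-12)
        grow[i] = g
        c = eff * (U - M) if (g and U > M) else 0.0
        dC[i] = c
        patch_n_need[q] += c * n_per_C

    # nitrogen re-limitation via biomass stoichiometry
    for q in range(n_patch):
        if patch_n_need[q] > amm[q] and patch_n_need[q] > 0.0:
            share[q] = amm[q] / patch_n_need[q]
        else:
            share[q] = 1.0

    respired = 0.0
    inv_yield = 1.0 / eff - 1.0
    for i in range(n):
        q = patch[i]
        M = mcoef * biomass[i]
        if grow[i]:
            c = dC[i] * share[q]
            glc[q] -= M + c / eff  # unused glucose demand is not taken
            amm[q] -= c * n_per_C
            respired += M + c * inv_yield
            biomass[i] += c
            starv[i] = 0.0
        else:
            glc[q] -= demand[i]  # all realized uptake respired, no growth
            respired += demand[i]
            starv[i] += dt

    for q in range(n_patch):  # clip last-ulp negatives from shared uptake
        if glc[q] < 0.0:
            glc[q] = 0.0
        if amm[q] < 0.0:
            amm[q] = 0.0
    return respired


def _metabolize_all(world: WorldState, p: ParameterSet) -> None:
    world.respired_C += _metabolize_kernel(
        world.patch,
        world.biomass,
        world.starv_min,
        world.glucose_C.ravel(),
        world.ammonium_N.ravel(),
        world.glucose_gC_per_mM,
        world.ks_mM,
        p.umax_pa,
        p.steptime,
        p.efficiency,
        p.energy_maintenance_pa,
        STOICHIOMETRY.N_per_C,
    )


def _kill_starved(world: WorldState, p: ParameterSet) -> None:
    dead = world.starv_min > p.max_time_viability_pa
    if not dead.any():
        return
    world.dead_biomass_C += float(world.biomass[dead].sum())
    keep = ~dead
    world.biomass = world.biomass[keep]
    world.birth_mass = world.birth_mass[keep]
    world.age_min = world.age_min[keep]
    world.starv_min = world.starv_min[keep]
    world.patch = world.patch[keep]
    world.ids = world.ids[keep]


def _local_space(counts: np.ndarray, pmax: int, side: int) -> np.ndarray:
    """Flat boolean: patch or any 8-neighbour has room (3x3 dilation)."""
    free = (counts < pmax).reshape(side, side)
    padded = np.zeros((side + 2, side + 2), dtype=bool)
    padded[1:-1, 1:-1] = free
    out = np.zeros((side, side), dtype=bool)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            out |= padded[dr:dr + side, dc:dc + side]
    return out.ravel()


def _divide(world: WorldState, p: ParameterSet) -> None:
    ready = np.flatnonzero(
        (world.biomass >= 2.0 * world.birth_mass) & (world.age_min >= p.rep_pa)
    )
    if ready.size == 0:
        return
    counts = world.patch_counts()
    if ready.size > 128:
        # deferred divisions pile up once the lattice saturates: drop
        # candidates with no room anywhere in their 3x3 neighbourhood
        ready = ready[_local_space(counts, p.pmax, world.grid_side)[world.patch[ready]]]
        if ready.size == 0:
            return
    new_patch_arr = np.empty(ready.size, dtype=np.int64)
    divided = np.zeros(ready.size, dtype=bool)

    # fast path: patches whose free room covers all their candidates
    homes = world.patch[ready]
    cand_per_patch = np.bincount(homes, minlength=counts.size)
    fits = (counts[homes] + cand_per_patch[homes]) <= p.pmax
    if fits.any():
        new_patch_arr[fits] = homes[fits]
        divided[fits] = True
        counts += np.bincount(homes[fits], minlength=counts.size)

    # contended remainder: shuffled order, spill to a random non-full neighbour
    rest = np.flatnonzero(~fits)
    if rest.size:
        rng = world.rng
        nbrs = world._nbr_table
        for j in rest[rng.permutation(rest.size)]:
            home = homes[j]
            if counts[home] < p.pmax:
                target = home
            else:
                cand = nbrs[home]
                cand = cand[(cand >= 0) & (counts[cand] < p.pmax)]
                if cand.size == 0:
                    continue  # all full: division deferred, mother keeps her mass
                target = int(cand[rng.integers(cand.size)])
            new_patch_arr[j] = target
            divided[j] = True
            counts[target] += 1

    idx = ready[divided]
    if idx.size == 0:
        return
    half = world.biomass[idx] / 2.0
    world.biomass[idx] = half
    world.birth_mass[idx] = half
    world.age_min[idx] = 0.0
    k = idx.size
    world.biomass = np.concatenate([world.biomass, half])
    world.birth_mass = np.concatenate([world.birth_mass, half])
    world.age_min = np.concatenate([world.age_min, np.zeros(k)])
    world.starv_min = np.concatenate([world.starv_min, np.zeros(k)])
    world.patch = np.concatenate([world.patch, new_patch_arr[divided]])
    world.ids = np.concatenate(
        [world.ids, np.arange(world.next_id, world.next_id + k, dtype=np.int64)]
    )
    world.next_id += k


def step(world: WorldState, p: ParameterSet | None = None) -> WorldState:
    """Advance the world by one tick (in place); returns the world."""
    if p is None:
        p = world.params
    world.glucose_C = diffuse_field(world.glucose_C, p.diffusion_coefficient)
    world.ammonium_N = diffuse_field(world.ammonium_N, p.diffusion_coefficient)
    if world.n_alive:
        _metabolize_all(world, p)
        _kill_starved(world, p)
        _divide(world, p)
        world.age_min += p.steptime
    world.tick += 1
    return world


def run(
    p: ParameterSet,
    seed: int,
    t_max_h: float = 18.0,
    patch_side_um: float = DEFAULT_PATCH_SIDE_UM,
    ks_mM: float = DEFAULT_KS_MM,
    dry_fraction: float = DEFAULT_DRY_FRACTION,
    return_world: bool = False,
):
    """Simulate ``t_max_h`` hours and return the population curve.

    The curve records the viable-cell count at tick 0 and after every tick
    (time axis in hours).  A given ``(p, seed)`` always reproduces the same
    curve.  Once the population hits zero the remaining counts are zero and
    the tick loop exits early.
    """
    if t_max_h <= 0:
        raise ValueError("t_max_h must be positive")
    world = initialize_world(p, seed, patch_side_um, ks_mM, dry_fraction)
    n_ticks = int(math.floor(t_max_h * 60.0 / p.steptime))
    counts = np.zeros(n_ticks + 1, dtype=np.int64)
    counts[0] = world.n_alive
    for t in range(1, n_ticks + 1):
        step(world, p)
        counts[t] = world.n_alive
        if counts[t] == 0:
            break
    time_h = np.arange(n_ticks + 1) * (p.steptime / 60.0)
    curve = PopulationCurve(time_h=time_h, population=counts, seed=seed)
    return (curve, world) if return_world else curve
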