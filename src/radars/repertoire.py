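"""Agent-based B-cell repertoire simulation in radial interaction space.

Clones live in a D-dimensional shape space: the *direction* of a clone's
unit vector encodes which antigen shapes it recognises, and its radius — the
binding free energy ΔG — encodes the resolution of that recognition.  A
clone engages an antigen only if the angular distance between them is below
the resolution cap θ(ΔG) = c/ΔG (higher affinity ⇒ narrower discrimination),
and then with receptor-occupancy probability [Ag]/([Ag] + K_D).

The life cycle per synchronous time step:

1. bone-marrow influx of naive clones at the base energy r₀·ε₀, a fraction
   of which are innate-like B1 cells that never mature further;
2. clonal expansion/death proportional to antigen engagement (logistic cap);
3. engaged clones at or above the system mean energy enter germinal centers
   (GC), recording their driving antigen;
4. GC clones iterate mutation–selection: an angular proposal is accepted only
   if it improves alignment with the driving antigen, each accepted cycle
   adding one noncovalent bond and ε₀·alignment of binding energy;
5. once the driving antigen is cleared (free level within a factor of the
   best clone's K_D) the GC cohort retracts: the top-affinity clone becomes
   the subnetwork's long-lived plasma cell (LLPC), the rest become memory
   B cells (MBC), excess effector cells are removed by apoptosis;
6. each antigen's free concentration relaxes geometrically toward the K_D of
   the best secreting clone covering it — the regulatory principle
   [Ag] ≈ K_D.

Binding energy never decreases along a lineage, cells are created only by
influx and division and removed only by death/apoptosis, and all randomness
flows from a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .thermo import ThermoContext


__all__ = [
    "Stage",
    "AntigenSite",
    "BCellClone",
    "SimulationConfig",
    "RepertoireState",
    "RepertoireSummary",
    "cap_half_angle",
    "init_space",
    "bone_marrow_influx",
    "engagement_probability",
    "step",
    "germinal_center_step",
    "retract",
    "update_antigen",
    "summarize_repertoire",
    "run_simulation",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class Stage(IntEnum):
    """B-cell differentiation stages (anatomical location is implicit)."""

    CLP = 0
    PRO_B = 1
    PRE_B = 2
    IMMATURE = 3
    NAIVE_B2 = 4
    B1 = 5
    GC = 6
    MBC = 7
    LLPC = 8
    SLPC = 9


@dataclass(frozen=True)
class AntigenSite:
    """One antigenic shape: a direction plus its availability."""

    direction: np.ndarray
    base_concentration: float
    free_concentration: float


@dataclass(frozen=True)
class BCellClone:
    """Row view of one clone in the repertoire."""

    id: int
    stage: Stage
    direction: Optional[np.ndarray]
    r_bonds: int
    dg: float
    size: int
    parent_id: int = -1
    driving_antigen: int = -1


def cap_half_angle(fraction: float, dim: int) -> float:
    """Half-angle of a spherical cap covering ``fraction`` of the unit sphere S^(dim-1)."""
    if not (0 < fraction < 1):
        raise ConfigError("cap fraction must be in (0, 1)")
    if dim < 2:
        raise ConfigError("need dim >= 2")
    total = integrate.quad(lambda t: math.sin(t) ** (dim - 2), 0.0, math.pi)[0]

    def covered(theta: float) -> float:
        return integrate.quad(lambda t: math.sin(t) ** (dim - 2), 0.0, theta)[0] / total

    return optimize.brentq(lambda th: covered(th) - fraction, 1e-6, math.pi - 1e-6)


@dataclass
class SimulationConfig:
    """Parameters of the interaction-space simulation.

    The dynamics are deliberately minimal; rates and sizes are free
    parameters of the model.  Defaults put the system in the regime where
    germinal-center maturation, retraction and antigen regulation all occur
    within a few hundred steps at desktop scale.

    Key parameters
    --------------
    shape_dim : dimensionality D of shape space (unit sphere of directions).
    n_antigens : number of sampled antigenic shapes.
    lam : rate λ of the exponential distribution of antigen availability.
    eps0 : binding energy gained per well-aligned noncovalent bond, kJ/mol;
        defaults to RT at the configured temperature (≈ 2.577 kJ/mol), so
        10–11 bonds reach the characteristic 27.67 kJ/mol system mean.
    angular_resolution_constant : c in θ(ΔG) = c/ΔG; defaults to the value
        making a fresh immature clone's cap cover ``cap_coverage`` of the
        sphere.
    mean_system_dg : fixed germinal-center entry threshold; ``None`` uses the
        live population mean energy (the system's "red circle").
    gc_trigger : engagement probability required for GC entry (receptor
        occupancy one-half by default).
    clearance_factor : an antigen counts as cleared once its free level is
        within this factor of the best clone's K_D.
    rho : per-step geometric relaxation rate of free antigen toward its
        regulated level.
    """

    shape_dim: int = 8
    n_antigens: int = 60
    lam: float = 1.6180339887498949
    influx_per_step: int = 20
    b1_fraction: float = 0.05
    b1_mode: str = "low"  # "low": B1 stay at base energy; "high": at b1_high_dg
    b1_high_dg: float = 27.67
    r0_bonds: int = 3
    eps0: Optional[float] = None
    temperature: float = 310.0
    division_rates: Dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.IMMATURE: 0.25,
            Stage.NAIVE_B2: 0.25,
            Stage.B1: 0.05,
            Stage.GC: 0.4,
        }
    )
    death_rates: Dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.IMMATURE: 0.08,
            Stage.NAIVE_B2: 0.08,
            Stage.GC: 0.05,
        }
    )
    carrying_capacity: int = 1000
    gc_trigger: float = 0.5
    gc_mutation_step: float = 0.15
    gc_cycles: int = 10
    angular_resolution_constant: Optional[float] = None
    cap_coverage: float = 0.01
    mean_system_dg: Optional[float] = None
    clearance_factor: float = 3.0
    rho: float = 0.5
    llpc_size: int = 10
    shell_width: Optional[float] = None
    seed: int = 0
    n_steps: int = 500

    def __post_init__(self) -> None:
        if self.shape_dim < 2:
            raise ConfigError(f"shape_dim must be >= 2, got {self.shape_dim}")
        if self.lam <= 0:
            raise ConfigError(f"lam must be positive, got {self.lam}")
        if self.n_antigens < 0 or self.influx_per_step < 0:
            raise ConfigError("counts must be non-negative")
        if not (0 <= self.b1_fraction <= 1):
            raise ConfigError("b1_fraction must be in [0, 1]")
        if self.b1_mode not in ("low", "high"):
            raise ConfigError("b1_mode must be 'low' or 'high'")
        if any(r < 0 for r in self.division_rates.values()) or any(
            r < 0 for r in self.death_rates.values()
        ):
            raise ConfigError("rates must be >= 0")
        if not (0 < self.rho <= 1):
            raise ConfigError("rho must be in (0, 1]")
        if self.eps0 is None:
            self.eps0 = self.thermo.rt
        if self.shell_width is None:
            self.shell_width = self.eps0
        if self.angular_resolution_constant is None:
            theta0 = cap_half_angle(self.cap_coverage, self.shape_dim)
            self.angular_resolution_constant = theta0 * self.base_dg
        if self.angular_resolution_constant <= 0:
            raise ConfigError("angular_resolution_constant must be positive")

    @property
    def thermo(self) -> ThermoContext:
        return ThermoContext(temperature=self.temperature)

    @property
    def base_dg(self) -> float:
        """Binding energy of a fresh bone-marrow emigrant, r₀·ε₀."""
        return self.r0_bonds * float(self.eps0)

    def theta(self, dg) -> np.ndarray | float:
        """Angular resolution cap θ(ΔG) = c/ΔG, clipped to [0, π]."""
        dg = np.asarray(dg, dtype=float)
        with np.errstate(divide="ignore"):
            th = np.where(dg > 0, self.angular_resolution_constant / dg, math.pi)
        out = np.minimum(th, math.pi)
        return out if out.ndim else float(out)

    def kd(self, dg) -> np.ndarray | float:
        """Dissociation constant exp(−ΔG/RT) in dimensionless concentration units."""
        out = np.exp(-np.asarray(dg, dtype=float) / self.thermo.rt)
        return out if out.ndim else float(out)


def _uniform_directions(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, dim))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


@dataclass
class RepertoireState:
    """Mutable simulation state: antigen panel, clone table, ledger, RNG."""

    config: SimulationConfig
    rng: np.random.Generator
    # antigen panel
    ag_directions: np.ndarray  # (n_antigens, D)
    ag_base: np.ndarray
    ag_free: np.ndarray
    # clone table (structure of arrays; rows are never deleted)
    directions: np.ndarray  # (n_clones, D)
    dg: np.ndarray
    r_bonds: np.ndarray
    size: np.ndarray
    stage: np.ndarray
    parent: np.ndarray
    driving: np.ndarray
    gc_age: np.ndarray
    alive: np.ndarray
    birth_step: np.ndarray
    t: int = 0
    # cell-conservation ledger
    cells_born: int = 0
    cells_died: int = 0
    stage_transits: Dict[str, int] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return int(self.dg.shape[0])

    def active(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def clone(self, i: int) -> BCellClone:
        return BCellClone(
            id=int(i),
            stage=Stage(int(self.stage[i])),
            direction=self.directions[i].copy(),
            r_bonds=int(self.r_bonds[i]),
            dg=float(self.dg[i]),
            size=int(self.size[i]),
            parent_id=int(self.parent[i]),
            driving_antigen=int(self.driving[i]),
        )

    def antigen(self, a: int) -> AntigenSite:
        return AntigenSite(
            direction=self.ag_directions[a].copy(),
            base_concentration=float(self.ag_base[a]),
            free_concentration=float(self.ag_free[a]),
        )

    def mean_dg(self) -> float:
        """Population mean binding energy over living clones (0 if empty)."""
        idx = self.active()
        return float(self.dg[idx].mean()) if idx.size else 0.0

    def _check_ledger(self) -> bool:
        return int(self.size[self.alive].sum()) == self.cells_born - self.cells_died


def init_space(config: SimulationConfig) -> RepertoireState:
    """Sample the antigen panel and return an empty repertoire.

    Antigen directions are uniform on the unit sphere in D dimensions and
    base availabilities are Exponential with rate λ; free levels start at
    base.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_a, d = config.n_antigens, config.shape_dim
    ag_dirs = _uniform_directions(n_a, d, rng) if n_a else np.empty((0, d))
    base = rng.exponential(scale=1.0 / config.lam, size=n_a)
    return RepertoireState(
        config=config,
        rng=rng,
        ag_directions=ag_dirs,
        ag_base=base,
        ag_free=base.copy(),
        directions=np.empty((0, d)),
        dg=np.empty(0),
        r_bonds=np.empty(0, dtype=int),
        size=np.empty(0, dtype=int),
        stage=np.empty(0, dtype=int),
        parent=np.empty(0, dtype=int),
        driving=np.empty(0, dtype=int),
        gc_age=np.empty(0, dtype=int),
        alive=np.empty(0, dtype=bool),
        birth_step=np.empty(0, dtype=int),
    )


def bone_marrow_influx(state: RepertoireState, n_new: int) -> RepertoireState:
    """Add ``n_new`` fresh clones with random directions at the base energy.

    Each new clone has r₀ bonds and ΔG = r₀·ε₀ exactly; a configured fraction
    is flagged B1 (innate-like, exempt from germinal centers), the rest enter
    as immature B2 cells.  The CLP→proB→preB→immature progression is recorded
    in the stage-transit ledger (those stages carry no interaction, r = 0 at
    the CLP origin).
    """
    if n_new < 0:
        raise ConfigError("n_new must be >= 0")
    if n_new == 0:
        return state
    cfg = state.config
    dirs = _uniform_directions(n_new, cfg.shape_dim, state.rng)
    is_b1 = state.rng.random(n_new) < cfg.b1_fraction
    dg = np.full(n_new, cfg.base_dg)
    if cfg.b1_mode == "high":
        dg[is_b1] = cfg.b1_high_dg
    stage = np.where(is_b1, int(Stage.B1), int(Stage.IMMATURE))

    state.directions = np.concatenate([state.directions, dirs])
    state.dg = np.concatenate([state.dg, dg])
    state.r_bonds = np.concatenate([state.r_bonds, np.full(n_new, cfg.r0_bonds)])
    state.size = np.concatenate([state.size, np.ones(n_new, dtype=int)])
    state.stage = np.concatenate([state.stage, stage])
    state.parent = np.concatenate([state.parent, np.full(n_new, -1)])
    state.driving = np.concatenate([state.driving, np.full(n_new, -1)])
    state.gc_age = np.concatenate([state.gc_age, np.zeros(n_new, dtype=int)])
    state.alive = np.concatenate([state.alive, np.ones(n_new, dtype=bool)])
    state.birth_step = np.concatenate([state.birth_step, np.full(n_new, state.t)])

    state.cells_born += n_new
    for s in ("CLP", "PRO_B", "PRE_B", "IMMATURE"):
        state.stage_transits[s] = state.stage_transits.get(s, 0) + n_new
    return state


def engagement_probability(
    clone: BCellClone, antigen: AntigenSite, config: SimulationConfig
) -> float:
    """Probability that a clone's receptor is productively engaged by an antigen.

    Zero outside the angular resolution cap θ(ΔG) = c/ΔG; inside the cap the
    receptor-occupancy form [Ag]/([Ag] + K_D), capped at 1.
    """
    if clone.direction is None:
        raise ConfigError("clone has no direction (progenitor stage)")
    cos = float(np.clip(np.dot(clone.direction, antigen.direction), -1.0, 1.0))
    if math.acos(cos) > config.theta(clone.dg):
        return 0.0
    free = antigen.free_concentration
    if free <= 0:
        return 0.0
    kd = config.kd(clone.dg)
    return min(free / (free + kd), 1.0)


def _engagement_matrix(
    state: RepertoireState, idx: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised engagement: returns (max engagement, argmax antigen) per clone."""
    cfg = state.config
    n = idx.size
    if n == 0 or cfg.n_antigens == 0:
        return np.zeros(n), np.full(n, -1)
    cos = np.clip(state.directions[idx] @ state.ag_directions.T, -1.0, 1.0)
    ang = np.arccos(cos)
    theta = np.asarray(cfg.theta(state.dg[idx]))[:, None]
    kd = np.asarray(cfg.kd(state.dg[idx]))[:, None]
    free = state.ag_free[None, :]
    with np.errstate(invalid="ignore"):
        occ = np.where(free > 0, free / (free + kd), 0.0)
    eng = np.where(ang <= theta, np.minimum(occ, 1.0), 0.0)
    best_a = eng.argmax(axis=1)
    return eng[np.arange(n), best_a], best_a


def germinal_center_step(state: RepertoireState, i: int) -> bool:
    """One mutation–selection cycle for GC clone ``i``; returns acceptance.

    A Gaussian angular proposal (sd ``gc_mutation_step``) around the current
    direction is accepted only if it strictly improves alignment with the
    driving antigen; acceptance adds one bond and ε₀·alignment of binding
    energy.  Rejected proposals leave the clone unchanged (strict selection),
    so energy is monotone along the trajectory.
    """
    cfg = state.config
    if Stage(int(state.stage[i])) is not Stage.GC:
        raise ConfigError(f"clone {i} is not in a germinal center")
    a = int(state.driving[i])
    target = state.ag_directions[a]
    cur = state.directions[i]
    align_cur = float(np.dot(cur, target))
    prop = cur + cfg.gc_mutation_step * state.rng.standard_normal(cfg.shape_dim)
    prop /= np.linalg.norm(prop)
    align_new = float(np.dot(prop, target))
    state.gc_age[i] += 1
    if align_new <= align_cur:
        return False
    state.directions[i] = prop
    state.r_bonds[i] += 1
    state.dg[i] += cfg.eps0 * max(align_new, 0.0)
    return True


def retract(state: RepertoireState) -> RepertoireState:
    """Convert matured GC cohorts into one LLPC plus memory cells.

    A cohort (all GC clones sharing a driving antigen) retracts once the
    antigen is cleared — its free level is within ``clearance_factor`` of the
    best clone's K_D — or the cohort has exhausted its GC cycle budget.  The
    highest-energy clone becomes the subnetwork's LLPC (displacing, by niche
    competition, any lower-energy incumbent); the rest become MBC at minimal
    size.  Excess effector cells are removed as apoptosis in the ledger.
    """
    cfg = state.config
    gc_idx = np.flatnonzero(state.alive & (state.stage == int(Stage.GC)))
    if gc_idx.size == 0:
        return state
    for a in np.unique(state.driving[gc_idx]):
        cohort = gc_idx[state.driving[gc_idx] == a]
        best = cohort[np.argmax(state.dg[cohort])]
        cleared = state.ag_free[a] <= cfg.clearance_factor * cfg.kd(state.dg[best])
        expired = bool(np.any(state.gc_age[cohort] >= cfg.gc_cycles))
        if not (cleared or expired):
            continue
        for i in cohort:
            if i == best:
                new_size = min(int(state.size[i]), cfg.llpc_size)
                state.cells_died += int(state.size[i]) - new_size
                state.size[i] = new_size
                state.stage[i] = int(Stage.LLPC)
                state.stage_transits["LLPC"] = state.stage_transits.get("LLPC", 0) + 1
            else:
                state.cells_died += int(state.size[i]) - 1
                state.size[i] = 1
                state.stage[i] = int(Stage.MBC)
                state.stage_transits["MBC"] = state.stage_transits.get("MBC", 0) + 1
        # niche competition: one LLPC per subnetwork, the strongest binder wins
        llpc = np.flatnonzero(
            state.alive & (state.stage == int(Stage.LLPC)) & (state.driving == a)
        )
        if llpc.size > 1:
            keep = llpc[np.argmax(state.dg[llpc])]
            for i in llpc:
                if i != keep:
                    state.cells_died += int(state.size[i])
                    state.size[i] = 0
                    state.alive[i] = False
    return state


def update_antigen(state: RepertoireState) -> RepertoireState:
    """Relax each antigen's free level toward its regulated value [Ag] ≈ K_D.

    The target is min(base, K_D of the best secreting clone covering the
    antigen); secreting clones are LLPC (within their angular cap) and GC
    cohorts acting on their driving antigen through short-lived effector
    output.  Antigens with no covering secretor relax back toward base.
    """
    cfg = state.config
    if cfg.n_antigens == 0:
        return state
    target = state.ag_base.copy()
    secretors = np.flatnonzero(
        state.alive
        & ((state.stage == int(Stage.LLPC)) | (state.stage == int(Stage.GC)))
    )
    if secretors.size:
        cos = np.clip(state.directions[secretors] @ state.ag_directions.T, -1.0, 1.0)
        within = np.arccos(cos) <= np.asarray(cfg.theta(state.dg[secretors]))[:, None]
        drv = state.driving[secretors]
        has_drv = drv >= 0
        within[np.flatnonzero(has_drv), drv[has_drv]] = True
        kd = np.asarray(cfg.kd(state.dg[secretors]))[:, None]
        best_kd = np.where(within, kd, np.inf).min(axis=0)
        covered = np.isfinite(best_kd)
        target[covered] = np.minimum(state.ag_base[covered], best_kd[covered])
    state.ag_free += cfg.rho * (target - state.ag_free)
    np.minimum(state.ag_free, state.ag_base, out=state.ag_free)
    return state


def step(state: RepertoireState) -> RepertoireState:
    """One synchronous update: influx, expansion, GC entry, GC cycles,
    retraction, antigen relaxation."""
    cfg = state.config

    bone_marrow_influx(state, cfg.influx_per_step)

    idx = state.active()
    eng, best_a = _engagement_matrix(state, idx)

    # clonal expansion and death, logistic near the carrying capacity
    stages = state.stage[idx]
    sizes = state.size[idx]
    div = np.array([cfg.division_rates.get(Stage(int(s)), 0.0) for s in stages])
    dth = np.array([cfg.death_rates.get(Stage(int(s)), 0.0) for s in stages])
    room = np.clip(1.0 - sizes / cfg.carrying_capacity, 0.0, 1.0)
    p_div = np.clip(div * eng * room, 0.0, 1.0)
    births = state.rng.binomial(sizes, p_div)
    deaths = state.rng.binomial(sizes, np.clip(dth, 0.0, 1.0))
    state.size[idx] = sizes + births - deaths
    state.cells_born += int(births.sum())
    state.cells_died += int(deaths.sum())
    extinct = idx[state.size[idx] <= 0]
    state.size[extinct] = 0
    state.alive[extinct] = False

    # germinal-center entry: engaged clones whose energy shell is at or above
    # the shell containing the system mean energy (the model's "red circle";
    # shells are the discrete iso-energy levels of interaction space)
    threshold = (
        cfg.mean_system_dg if cfg.mean_system_dg is not None else state.mean_dg()
    )
    threshold_shell = math.floor(threshold / cfg.shell_width)
    eligible = (
        state.alive[idx]
        & ((stages == int(Stage.IMMATURE)) | (stages == int(Stage.NAIVE_B2)))
        & (np.floor(state.dg[idx] / cfg.shell_width) >= threshold_shell)
        & (eng >= cfg.gc_trigger)
    )
    entrants = idx[eligible]
    state.stage[entrants] = int(Stage.GC)
    state.driving[entrants] = best_a[eligible]
    state.gc_age[entrants] = 0
    state.stage_transits["GC"] = state.stage_transits.get("GC", 0) + entrants.size

    for i in np.flatnonzero(state.alive & (state.stage == int(Stage.GC))):
        germinal_center_step(state, int(i))

    retract(state)
    update_antigen(state)

    # bookkeeping: surviving immature emigrants become naive B2 cells
    matured = state.alive & (state.stage == int(Stage.IMMATURE)) & (
        state.birth_step < state.t
    )
    state.stage[matured] = int(Stage.NAIVE_B2)
    state.t += 1
    return state


@dataclass(frozen=True)
class RepertoireSummary:
    """Aggregate view of a repertoire state."""

    stage_counts: Dict[str, int]
    cell_counts: Dict[str, int]
    shell_counts: Dict[int, int]
    dg_histogram: Tuple[np.ndarray, np.ndarray]
    clones: pd.DataFrame  # id, stage, dg, r_bonds, size, parent, subnetwork, k_sys
    mean_dg: float


def summarize_repertoire(state: RepertoireState) -> RepertoireSummary:
    """Per-stage and per-energy-shell counts plus the clone/K_sys table.

    K_sys uses the living population's mean energy as <ΔG>:
    K_sys = exp((ΔG − <ΔG>)/RT).  Empty repertoires yield all-zero tables.
    """
    cfg = state.config
    idx = state.active()
    stage_counts = {s.name: 0 for s in Stage}
    cell_counts = {s.name: 0 for s in Stage}
    for i in idx:
        name = Stage(int(state.stage[i])).name
        stage_counts[name] += 1
        cell_counts[name] += int(state.size[i])
    shells = (state.dg[idx] // cfg.shell_width).astype(int) if idx.size else np.empty(0, int)
    shell_counts: Dict[int, int] = {}
    for s in shells:
        shell_counts[int(s)] = shell_counts.get(int(s), 0) + 1
    hist = np.histogram(state.dg[idx], bins=20) if idx.size else (
        np.zeros(20, dtype=int),
        np.linspace(0, 1, 21),
    )
    mean_dg = state.mean_dg()
    rt = cfg.thermo.rt
    k_sys = np.exp((state.dg[idx] - mean_dg) / rt) if idx.size else np.empty(0)
    clones = pd.DataFrame(
        {
            "id": idx,
            "stage": [Stage(int(state.stage[i])).name for i in idx],
            "dg": state.dg[idx],
            "r_bonds": state.r_bonds[idx],
            "size": state.size[idx],
            "parent": state.parent[idx],
            "subnetwork": state.driving[idx],
            "shell": shells,
            "k_sys": k_sys,
        }
    )
    return RepertoireSummary(
        stage_counts=stage_counts,
        cell_counts=cell_counts,
        shell_counts=shell_counts,
        dg_histogram=hist,
        clones=clones,
        mean_dg=mean_dg,
    )


def run_simulation(config: SimulationConfig) -> RepertoireState:
    """Run ``config.n_steps`` synchronous steps from an empty repertoire."""
    state = init_space(config)
    for _ in range(config.n_steps):
        step(state)
    return state


def clones_dataframe(state: RepertoireState, alive_only: bool = True) -> pd.DataFrame:
    """Full clone table for export (CSV-friendly, no array columns)."""
    idx = state.active() if alive_only else np.arange(state.n_clones)
    return pd.DataFrame(
        {
            "id": idx,
            "stage": [Stage(int(state.stage[i])).name for i in idx],
            "dg": state.dg[idx],
            "r_bonds": state.r_bonds[idx],
            "size": state.size[idx],
            "parent": state.parent[idx],
            "subnetwork": state.driving[idx],
            "birth_step": state.birth_step[idx],
        }
    )


def antigens_dataframe(state: RepertoireState) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": np.arange(state.config.n_antigens),
            "base_concentration": state.ag_base,
            "free_concentration": state.ag_free,
        }
    )
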