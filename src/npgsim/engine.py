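"""Fixed-time-step lattice Monte Carlo engine for integrin clustering.

A 6 x 6 um^2 patch of cell membrane is discretised into a 100 x 100
periodic square lattice (60 nm sites); 1000 integrins are placed at
random, one ECM ligand sits on every site, and each 10 ms step every
integrin (in freshly shuffled order) either performs at most one
reaction event or attempts one diffusion hop to a free 4-neighbour site.

The reaction ladder is INACTIVE <-> ACTIVE <-> BOUND <-> ASSOCIATED with
adjacent-rung transitions only: a bound integrin cannot deactivate
without unbinding first, and an associated (clustered) integrin must
disassociate before it can unbind or move.  Association is a contact
reaction: a BOUND integrin with at least one BOUND or ASSOCIATED
4-neighbour may convert to ASSOCIATED, recruiting one bound neighbour if
no associated one exists, so clusters nucleate pairwise and grow by
adjacency.  After every sweep an orphan-cleanup pass demotes ASSOCIATED
integrins left without an ASSOCIATED neighbour, keeping the associated
population equal to the union of lattice-connected clusters of size >= 2.

Each reversible reaction pair is sampled with its exact two-state
discrete-time transition probabilities (see
:func:`npgsim.energy.pair_step_probabilities`), so the equilibrium ratio
of every rung equals the prescribed Boltzmann factor at the full 10 ms
step.  States are encoded INACTIVE=0, ACTIVE=1, BOUND=2, ASSOCIATED=3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from numba import njit

from .energy import EnergyParams, FLAT_GOLD, binding_energy, association_energy, \
    pair_step_probabilities, scenario_params
from .substrate import SubstrateField

__all__ = [
    "INACTIVE", "ACTIVE", "BOUND", "ASSOCIATED", "STATE_NAMES",
    "MembraneLattice", "SimConfig", "LatticeState", "Trajectory",
    "initialize", "mc_step", "run_steps", "run_to_equilibrium",
    "map_substrate_to_lattice", "ConfigurationError",
]

INACTIVE, ACTIVE, BOUND, ASSOCIATED = 0, 1, 2, 3
STATE_NAMES = ("INACTIVE", "ACTIVE", "BOUND", "ASSOCIATED")


class ConfigurationError(ValueError):
    """Simulation configuration is invalid or numerically inconsistent."""


@dataclass(frozen=True)
class MembraneLattice:
    """Geometry of the membrane patch: periodic square grid, one ECM
    ligand per site, per-site gold concentration."""

    n_rows: int = 100
    n_cols: int = 100
    site_spacing: float = 60.0   # nm; 6 um / 100 sites
    ligand_per_site: int = 1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("lattice dimensions must be positive")

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run."""

    n_integrins: int = 1000
    lattice: MembraneLattice = dc_field(default_factory=MembraneLattice)
    seed: int = 0
    scenario: str = "fig5c"
    pore_nm: float = FLAT_GOLD          # substrate pore size; FLAT_GOLD = flat control
    c_mode: str = "uniform"             # {"uniform", "field"}
    substrate: Optional[SubstrateField] = None
    binding_enabled: bool = True
    association_enabled: bool = True
    diffusion_enabled: bool = True
    max_steps: int = 200_000
    min_steps: int = 0                  # never declare equilibrium before this
    equil_window: int = 5_000
    equil_tolerance: float = 1e-3       # relative slope per 1000 steps
    record_every: int = 50

    def __post_init__(self) -> None:
        if self.n_integrins < 0:
            raise ConfigurationError("n_integrins must be >= 0")
        if self.n_integrins > self.lattice.n_sites:
            raise ConfigurationError(
                f"{self.n_integrins} integrins exceed {self.lattice.n_sites} sites"
            )
        if self.c_mode not in ("uniform", "field"):
            raise ConfigurationError(f"c_mode must be 'uniform' or 'field', got {self.c_mode!r}")
        if self.c_mode == "field" and self.substrate is None:
            raise ConfigurationError("c_mode='field' requires a substrate field")
        if self.equil_window >= self.max_steps:
            raise ConfigurationError("equil_window must be smaller than max_steps")


def map_substrate_to_lattice(
    field: SubstrateField,
    n_rows: int = 100,
    n_cols: int = 100,
    site_spacing: float = 60.0,
    tile: bool = True,
) -> np.ndarray:
    """Average a substrate concentration field onto lattice sites.

    Each 60 nm site takes the mean of the field pixels it covers.  Fields
    smaller than the membrane are tiled periodically (both the field and
    the membrane are periodic); with ``tile=False`` an undersized field is
    an error.
    """
    if field.kind == "flat":
        return np.ones((n_rows, n_cols))
    px = field.pixel_size
    need_r = n_rows * site_spacing
    need_c = n_cols * site_spacing
    if not tile and (field.extent_nm < need_r or field.extent_nm < need_c):
        raise ConfigurationError(
            f"field extent {field.extent_nm:.0f} nm smaller than membrane "
            f"{need_r:.0f} nm and tiling is disabled"
        )
    conc = np.clip(field.concentration, 0.0, 1.0)
    reps_r = int(np.ceil(need_r / field.extent_nm))
    reps_c = int(np.ceil(need_c / (conc.shape[1] * px)))
    big = np.tile(conc, (max(reps_r, 1), max(reps_c, 1)))
    # assign each pixel (by centre) to the lattice site it falls in
    pr = (np.arange(big.shape[0]) + 0.5) * px
    pc = (np.arange(big.shape[1]) + 0.5) * px
    sr = np.minimum((pr // site_spacing).astype(np.int64), n_rows - 1)
    sc = np.minimum((pc // site_spacing).astype(np.int64), n_cols - 1)
    keep_r = pr < need_r
    keep_c = pc < need_c
    big = big[keep_r][:, keep_c]
    sr, sc = sr[keep_r], sc[keep_c]
    sums = np.zeros((n_rows, n_cols))
    counts = np.zeros((n_rows, n_cols))
    np.add.at(sums, (sr[:, None], sc[None, :]), big)
    np.add.at(counts, (sr[:, None], sc[None, :]), 1.0)
    if np.any(counts == 0):
        raise ConfigurationError(
            "substrate field too coarse: some lattice sites receive no pixels"
        )
    return sums / counts


@dataclass
class LatticeState:
    """Mutable state of a running simulation."""

    config: SimConfig
    params: EnergyParams
    occ: np.ndarray          # (n_rows, n_cols) int32, integrin index or -1
    row: np.ndarray          # (n,) int32
    col: np.ndarray          # (n,) int32
    state: np.ndarray        # (n,) int8
    site_c: np.ndarray       # (n_rows, n_cols) gold concentration per site
    p_act: float
    p_inact: float
    p_bind: np.ndarray       # per-site probabilities
    p_unbind: np.ndarray
    p_assoc: np.ndarray
    p_disassoc: np.ndarray
    rng: np.random.Generator
    step_count: int = 0

    @property
    def n_integrins(self) -> int:
        return len(self.state)

    def counts(self) -> tuple[int, int, int, int]:
        """(inactive, active, bound, associated) integrin counts."""
        c = np.bincount(self.state, minlength=4)
        return int(c[0]), int(c[1]), int(c[2]), int(c[3])


def _probability_tables(config: SimConfig, params: EnergyParams):
    """Per-site event probabilities from the energy model."""
    lat = config.lattice
    if config.c_mode == "uniform":
        site_c = np.ones((lat.n_rows, lat.n_cols))
    else:
        site_c = map_substrate_to_lattice(
            config.substrate, lat.n_rows, lat.n_cols, lat.site_spacing
        )
    dt = params.dt
    k_a_minus = params.k_a_plus * math.exp(params.E_a)
    p_act, p_inact = pair_step_probabilities(params.k_a_plus, k_a_minus, dt)

    shape = site_c.shape
    p_bind = np.zeros(shape)
    p_unbind = np.zeros(shape)
    p_assoc = np.zeros(shape)
    p_disassoc = np.zeros(shape)
    if config.binding_enabled or config.association_enabled:
        # energies depend on the site only through c; evaluate per unique c
        for c_val in np.unique(site_c):
            m = site_c == c_val
            if config.binding_enabled:
                e_b = binding_energy(config.pore_nm, float(c_val), params)
                k_b_minus = params.k_b_plus * math.exp(-e_b)
                pb, pu = pair_step_probabilities(params.k_b_plus, k_b_minus, dt)
                p_bind[m], p_unbind[m] = pb, pu
            if config.association_enabled:
                e_c = association_energy(config.pore_nm, float(c_val), params)
                k_c_minus = params.k_c_plus * math.exp(-e_c)
                pa, pd = pair_step_probabilities(params.k_c_plus, k_c_minus, dt)
                p_assoc[m], p_disassoc[m] = pa, pd

    worst = max(
        p_act,
        p_disassoc.max(),
        p_inact + p_bind.max(),
        p_unbind.max() + p_assoc.max(),
    )
    if worst > 1.0:
        raise ConfigurationError(
            f"channel probabilities sum to {worst:.3f} > 1 for dt={dt}; reduce dt"
        )
    return site_c, p_act, p_inact, p_bind, p_unbind, p_assoc, p_disassoc


def initialize(config: SimConfig, params: EnergyParams | None = None) -> LatticeState:
    """Place ``n_integrins`` uniformly at random on distinct sites, all
    INACTIVE; deterministic for a fixed seed."""
    if params is None:
        params = scenario_params(config.scenario)
    lat = config.lattice
    rng = np.random.default_rng(config.seed)
    sites = rng.choice(lat.n_sites, size=config.n_integrins, replace=False)
    row = (sites // lat.n_cols).astype(np.int32)
    col = (sites % lat.n_cols).astype(np.int32)
    occ = np.full((lat.n_rows, lat.n_cols), -1, dtype=np.int32)
    occ[row, col] = np.arange(config.n_integrins, dtype=np.int32)
    state = np.zeros(config.n_integrins, dtype=np.int8)
    site_c, p_act, p_inact, p_bind, p_unbind, p_assoc, p_disassoc = \
        _probability_tables(config, params)
    return LatticeState(
        config=config, params=params, occ=occ, row=row, col=col, state=state,
        site_c=site_c, p_act=p_act, p_inact=p_inact, p_bind=p_bind,
        p_unbind=p_unbind, p_assoc=p_assoc, p_disassoc=p_disassoc, rng=rng,
    )


@njit(cache=True)
def _kernel(occ, row, col, state, p_act, p_inact, p_bind, p_unbind, p_assoc,
            p_disassoc, diffuse, n_steps, record_every, rec, rng, order):
    n_rows, n_cols = occ.shape
    n = state.shape[0]
    n_rec = 0
    dr = np.array([-1, 1, 0, 0], dtype=np.int64)
    dc = np.array([0, 0, -1, 1], dtype=np.int64)
    for step in range(n_steps):
        # Fisher-Yates shuffle of the update order
        for i in range(n - 1, 0, -1):
            j = rng.integers(0, i + 1)
            tmp = order[i]; order[i] = order[j]; order[j] = tmp
        for oi in range(n):
            idx = order[oi]
            s = state[idx]
            r = row[idx]; c = col[idx]
            u = rng.random()
            fired = False
            if s == 0:                                   # INACTIVE -> ACTIVE
                if u < p_act:
                    state[idx] = 1
                    fired = True
            elif s == 1:                                 # ACTIVE -> INACTIVE | BOUND
                if u < p_inact:
                    state[idx] = 0
                    fired = True
                elif u < p_inact + p_bind[r, c]:
                    state[idx] = 2
                    fired = True
            elif s == 2:                                 # BOUND -> ACTIVE | ASSOCIATED
                if u < p_unbind[r, c]:
                    state[idx] = 1
                    fired = True
                else:
                    # association needs a BOUND or ASSOCIATED 4-neighbour
                    n_elig = 0
                    n_assoc_nb = 0
                    elig = np.empty(4, dtype=np.int64)
                    for d in range(4):
                        rr = (r + dr[d]) % n_rows
                        cc = (c + dc[d]) % n_cols
                        nb = occ[rr, cc]
                        if nb >= 0:
                            if state[nb] == 3:
                                n_assoc_nb += 1
                            elif state[nb] == 2:
                                elig[n_elig] = nb
                                n_elig += 1
                    if n_assoc_nb + n_elig > 0 and u < p_unbind[r, c] + p_assoc[r, c]:
                        state[idx] = 3
                        fired = True
                        if n_assoc_nb == 0:
                            # nucleate pairwise: recruit one bound neighbour
                            pick = elig[rng.integers(0, n_elig)]
                            state[pick] = 3
            else:                                        # ASSOCIATED -> BOUND
                if u < p_disassoc[r, c]:
                    state[idx] = 2
                    fired = True
            if diffuse and not fired and state[idx] != 3:
                d = rng.integers(0, 4)
                rr = (r + dr[d]) % n_rows
                cc = (c + dc[d]) % n_cols
                if occ[rr, cc] < 0:
                    occ[r, c] = -1
                    occ[rr, cc] = idx
                    row[idx] = rr
                    col[idx] = cc
        # orphan cleanup: ASSOCIATED with no ASSOCIATED neighbour -> BOUND
        changed = True
        while changed:
            changed = False
            for idx in range(n):
                if state[idx] == 3:
                    has = False
                    for d in range(4):
                        rr = (row[idx] + dr[d]) % n_rows
                        cc = (col[idx] + dc[d]) % n_cols
                        nb = occ[rr, cc]
                        if nb >= 0 and nb != idx and state[nb] == 3:
                            has = True
                            break
                    if not has:
                        state[idx] = 2
                        changed = True
        if record_every > 0 and (step + 1) % record_every == 0:
            n_a = 0; n_b = 0; n_s = 0
            for idx in range(n):
                if state[idx] == 1:
                    n_a += 1
                elif state[idx] == 2:
                    n_b += 1
                elif state[idx] == 3:
                    n_s += 1
            rec[n_rec, 0] = step + 1
            rec[n_rec, 1] = n_a
            rec[n_rec, 2] = n_b
            rec[n_rec, 3] = n_s
            n_rec += 1
    return n_rec


def run_steps(st: LatticeState, n_steps: int, record_every: int = 0) -> np.ndarray:
    """Advance the state by ``n_steps`` Monte Carlo sweeps.

    Returns an array of checkpoint rows (step, n_active, n_bound,
    n_associated) relative step indices offset by the state's current step
    count; empty if ``record_every`` is 0.
    """
    n_rec = n_steps // record_every if record_every > 0 else 0
    rec = np.zeros((max(n_rec, 1), 4), dtype=np.int64)
    order = np.arange(st.n_integrins, dtype=np.int64)
    if st.n_integrins > 0 and n_steps > 0:
        got = _kernel(
            st.occ, st.row, st.col, st.state, st.p_act, st.p_inact, st.p_bind,
            st.p_unbind, st.p_assoc, st.p_disassoc, st.config.diffusion_enabled,
            n_steps, record_every, rec, st.rng, order,
        )
    else:
        got = 0
    rec = rec[:got]
    rec[:, 0] += st.step_count
    st.step_count += n_steps
    return rec


def mc_step(st: LatticeState) -> LatticeState:
    """Advance the state by one sweep (all integrins updated once, in a
    freshly shuffled order, followed by orphan cleanup)."""
    run_steps(st, 1)
    return st


@dataclass(frozen=True)
class Trajectory:
    """Checkpoint record of one run plus its final state."""

    steps: np.ndarray        # checkpoint step indices
    n_active: np.ndarray
    n_bound: np.ndarray
    n_associated: np.ndarray
    final_state: LatticeState
    seed: int
    equilibrated: bool
    equil_step: int          # step at which the slope test passed (or max_steps)
    slope: float             # last measured relative slope per 1000 steps

    @property
    def n_inactive(self) -> np.ndarray:
        n = self.final_state.n_integrins
        return n - self.n_active - self.n_bound - self.n_associated


def _window_slope(steps: np.ndarray, assoc: np.ndarray) -> float:
    """|d assoc / d step| * 1000 / max(mean assoc, 1): relative drift per
    1000 steps of the associated count."""
    if len(steps) < 2:
        return math.inf
    slope = np.polyfit(steps.astype(float), assoc.astype(float), 1)[0]
    return abs(slope) * 1000.0 / max(float(assoc.mean()), 1.0)


def run_to_equilibrium(
    config: SimConfig, params: EnergyParams | None = None
) -> Trajectory:
    """Run until the associated count stops drifting, or ``max_steps``.

    Equilibrium is declared when the least-squares slope of the associated
    count over the trailing ``equil_window`` steps falls below
    ``equil_tolerance`` (relative change per 1000 steps), but never before
    ``min_steps`` — setting ``min_steps = max_steps`` yields fixed-duration
    runs, which is how the scenario sweep compares conditions (the
    associated count turns stationary within ~10^4 steps while the
    cluster-size distribution keeps ripening much longer, so replicates are
    only comparable at equal simulated time).  A run that hits ``max_steps``
    without passing the test is returned flagged ``equilibrated=False``,
    never silently accepted.
    """
    st = initialize(config, params)
    if st.n_integrins == 0:
        empty = np.zeros(0, dtype=np.int64)
        return Trajectory(empty, empty, empty, empty, st, config.seed, True, 0, 0.0)
    rec_all: list[np.ndarray] = []
    slope = math.inf
    equilibrated = False
    chunk = max(config.equil_window // 2, config.record_every)
    while st.step_count < config.max_steps:
        n_chunk = min(chunk, config.max_steps - st.step_count)
        rec_all.append(run_steps(st, n_chunk, config.record_every))
        if st.step_count < max(config.equil_window, config.min_steps):
            continue
        rec = np.concatenate(rec_all)
        tail = rec[rec[:, 0] > st.step_count - config.equil_window]
        slope = _window_slope(tail[:, 0], tail[:, 3])
        if slope < config.equil_tolerance:
            equilibrated = True
            break
    rec = np.concatenate(rec_all) if rec_all else np.zeros((0, 4), dtype=np.int64)
    return Trajectory(
        steps=rec[:, 0], n_active=rec[:, 1], n_bound=rec[:, 2],
        n_associated=rec[:, 3], final_state=st, seed=config.seed,
        equilibrated=equilibrated, equil_step=st.step_count, slope=slope,
    )
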