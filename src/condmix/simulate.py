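"""Monte Carlo protocol driver: equilibration, annealing, production sampling.

The protocol mirrors the three-phase design used for the condensate
simulations: (1) ``t_EQ`` steps of high-temperature equilibration at
T = T_EQ with the central constraining potential on and all anisotropic
(bond) interactions off; (2) exponential annealing
T(t) = T0 + T_EQ exp(-4 t / t_EQ) with interactions on and the constraint
active until the decay term drops below the threshold; (3) production at
T0 with the constraint off.  Samples are recorded every ``f_data`` steps
and, by default, only retained from the last half of the annealing +
production window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .config import SimulationConfig, sample_schedule
from .lattice import LatticeState, init_state, total_energy
from .models import InteractionModel


@dataclass
class TrajectorySample:
    """Snapshot of one production sample."""

    mc_step: int
    temperature: float
    positions: np.ndarray  # (N, 3) int64
    bonds: np.ndarray      # (N,) int64
    total_energy: float


def _constraint_mode(config: SimulationConfig) -> int:
    if config.R_B is None and config.constraint_form == "heaviside_quadratic":
        return _kernel.C_OFF
    return (_kernel.C_HEAVISIDE
            if config.constraint_form == "heaviside_quadratic"
            else _kernel.C_DELTA)


def metropolis_acceptance(dE: float, T: float) -> float:
    """min(1, exp(-dE/T)) — exposed for tests and documentation."""
    return min(1.0, float(np.exp(-dE / T)))


def mc_sweep(state: LatticeState, model: InteractionModel, T: float,
             weights: np.ndarray | None = None,
             rng_seed: int | None = None,
             n_attempts: int | None = None,
             aniso_on: bool = True,
             constraint_mode: int = _kernel.C_OFF,
             R_B: float = 0.0, T0: float = 1.0) -> float:
    """Run one sweep (N move attempts) of Metropolis dynamics in place.

    Returns the interaction-energy change accumulated by the kernel's
    incremental bookkeeping.  Seed the kernel RNG via ``rng_seed`` (pass
    None to continue the current stream).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if weights is None:
        w = np.ones(6) / 6.0
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    if rng_seed is not None:
        _kernel.seed_rng(rng_seed)
    n = n_attempts if n_attempts is not None else state.n_beads
    dE = _kernel.run_steps(
        state.pos, state.typ, state.chain_of, state.chain_start,
        state.chain_len, state.bond, state.occ, state.L,
        model.anisotropic_matrix, model.isotropic_matrix,
        np.cumsum(w), aniso_on, constraint_mode, R_B,
        T, False, T0, 0.0, 1.0, 0, 0, n, 0.0)
    return float(dE)


def run_protocol(config: SimulationConfig, model: InteractionModel,
                 replicate: int = 0,
                 return_state: bool = False):
    """Execute the full protocol for one replicate; return the samples.

    Replicate r uses seed ``config.rng_seed + r`` for both placement and
    the move stream.  Samples are listed in step order; with last-half
    sampling their count is (t_total/2)/f_data.
    """
    seed = int(config.rng_seed) + int(replicate)
    state = init_state(config, seed)
    sched = config.schedule()
    cmode = _constraint_mode(config)
    w = config.weight_vector()
    cum_w = np.cumsum(w)
    aniso = model.anisotropic_matrix
    iso = model.isotropic_matrix
    RB = config.R_B if config.R_B is not None else 0.0
    T0 = config.T_star
    TEQ = config.T_EQ

    _kernel.seed_rng(seed % (2 ** 31))
    E0 = _kernel.interaction_energy(state.pos, state.typ, state.bond,
                                    state.occ, state.L, aniso, iso)
    # phase 1: equilibration, constraint on, anisotropic interactions off
    E = _kernel.run_steps(state.pos, state.typ, state.chain_of,
                          state.chain_start, state.chain_len, state.bond,
                          state.occ, state.L, aniso, iso, cum_w,
                          False, cmode, RB, TEQ, False, T0, TEQ,
                          float(config.t_EQ), 0, 0, int(config.t_EQ), float(E0))

    # phase 2+3: annealing to T0, then production; constraint off and
    # temperature clamped at the threshold crossing (rounded up to the next
    # f_data boundary so the switch coincides with a sampling interval)
    t_clamp = sched.clamp_step
    t_clamp = ((t_clamp + config.f_data - 1) // config.f_data) * config.f_data
    steps = sample_schedule(config)
    all_marks = np.arange(config.f_data, config.t_total + 1, config.f_data,
                          dtype=np.int64)
    keep = set(int(s) for s in steps)
    samples: list[TrajectorySample] = []
    t_prev = 0
    for mark in all_marks:
        E = _kernel.run_steps(state.pos, state.typ, state.chain_of,
                              state.chain_start, state.chain_len, state.bond,
                              state.occ, state.L, aniso, iso, cum_w,
                              True, cmode, RB, T0, True, T0, TEQ,
                              float(config.t_EQ), t_clamp,
                              int(t_prev), int(mark - t_prev), E)
        t_prev = mark
        if int(mark) in keep:
            from .config import anneal_temperature
            T_now = anneal_temperature(mark, sched)
            cm_now = _kernel.C_OFF if mark >= t_clamp else cmode
            e_tot = E + _kernel.constraint_energy(state.pos, state.L, cm_now,
                                                  T_now, T0, RB)
            samples.append(TrajectorySample(
                mc_step=int(mark), temperature=float(T_now),
                positions=state.pos.copy(), bonds=state.bond.copy(),
                total_energy=float(e_tot)))
    if return_state:
        return samples, state, E
    return samples


def run_replicates(config: SimulationConfig, model: InteractionModel):
    """All replicates of a config; returns {replicate: samples}."""
    return {r: run_protocol(config, model, replicate=r)
            for r in range(config.replicate_count)}
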