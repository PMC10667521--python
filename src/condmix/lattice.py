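"""Lattice state container, random initialization, and energy evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .config import SimulationConfig
from .models import InteractionModel, STICKER_INDEX


@dataclass
class LatticeState:
    """Positions, chain topology, and sticker bonds on a periodic cubic lattice.

    Invariants (checked by :meth:`validate`): at most one bead per site;
    consecutive beads of a chain within linker reach; each bead in at most
    one anisotropic bond, bonds mutual and within the contact radius.
    """

    L: int
    pos: np.ndarray          # (N, 3) int64
    typ: np.ndarray          # (N,) int64 sticker class
    chain_of: np.ndarray     # (N,) int64
    chain_start: np.ndarray  # (M,) int64
    chain_len: np.ndarray    # (M,) int64
    species_of_chain: np.ndarray  # (M,) int64 index into config.species
    bond: np.ndarray         # (N,) int64, partner or -1
    occ: np.ndarray = field(default=None)  # (L^3,) int64 site -> bead

    def __post_init__(self):
        if self.occ is None:
            self.occ = self._build_occ()

    def _build_occ(self) -> np.ndarray:
        occ = np.full(self.L ** 3, -1, dtype=np.int64)
        idx = (self.pos[:, 0] * self.L + self.pos[:, 1]) * self.L + self.pos[:, 2]
        if len(np.unique(idx)) != len(idx):
            raise ValueError("excluded volume violated: duplicate site occupancy")
        occ[idx] = np.arange(len(idx))
        return occ

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def n_chains(self) -> int:
        return self.chain_start.shape[0]

    def copy(self) -> "LatticeState":
        return LatticeState(self.L, self.pos.copy(), self.typ.copy(),
                            self.chain_of.copy(), self.chain_start.copy(),
                            self.chain_len.copy(), self.species_of_chain.copy(),
                            self.bond.copy(), self.occ.copy())

    def min_image_d2(self, i: int, j: int) -> int:
        d = (self.pos[i] - self.pos[j]) % self.L
        d = np.where(2 * d > self.L, d - self.L, d)
        return int((d ** 2).sum())

    def validate(self) -> None:
        """Raise AssertionError on any violated state invariant."""
        occ = self._build_occ()
        assert np.array_equal(occ, self.occ), "occupancy index out of sync"
        for c in range(self.n_chains):
            s, ln = self.chain_start[c], self.chain_len[c]
            for b in range(s, s + ln - 1):
                assert self.min_image_d2(b, b + 1) <= _kernel.LINKER_D2, \
                    f"linker overstretched between beads {b},{b + 1}"
        bonded = np.flatnonzero(self.bond >= 0)
        for i in bonded:
            j = self.bond[i]
            assert self.bond[j] == i, f"bond not mutual: {i}<->{j}"
            assert self.min_image_d2(i, int(j)) <= _kernel.CONTACT_D2, \
                f"bond {i}-{j} beyond contact radius"


def init_state(config: SimulationConfig, seed: int,
               max_restarts: int = 200) -> LatticeState:
    """Place all molecules at random without collisions, empty bond set.

    Chains are grown bead by bead with uniformly chosen linker offsets;
    a molecule that walks itself into a dead end is retried, and the whole
    placement restarts (bounded) on persistently over-dense configurations.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    L = config.lattice_size
    N = config.total_beads

    typ, chain_of, chain_start, chain_len, species_of_chain = [], [], [], [], []
    b = 0
    for si, (sp, n_mol) in enumerate(zip(config.species, config.molecule_counts)):
        t = STICKER_INDEX[sp.sticker_type]
        for _ in range(n_mol):
            chain_start.append(b)
            chain_len.append(sp.bead_count)
            species_of_chain.append(si)
            for k in range(sp.bead_count):
                typ.append(t)
                chain_of.append(len(chain_start) - 1)
                b += 1
    typ = np.array(typ, dtype=np.int64)
    chain_of = np.array(chain_of, dtype=np.int64)
    chain_start = np.array(chain_start, dtype=np.int64)
    chain_len = np.array(chain_len, dtype=np.int64)
    species_of_chain = np.array(species_of_chain, dtype=np.int64)

    ball = _kernel.BALL32
    for _ in range(max_restarts):
        occupied = np.zeros((L, L, L), dtype=bool)
        pos = np.zeros((N, 3), dtype=np.int64)
        ok = True
        for c in range(len(chain_start)):
            s, ln = chain_start[c], chain_len[c]
            placed = False
            for _attempt in range(500):
                p0 = rng.integers(0, L, size=3)
                if occupied[tuple(p0)]:
                    continue
                trial = [p0]
                for _k in range(ln - 1):
                    prev = trial[-1]
                    order = rng.permutation(len(ball))
                    nxt = None
                    for oi in order:
                        cand = (prev + ball[oi]) % L
                        if not occupied[tuple(cand)] and \
                                not any(np.array_equal(cand, q) for q in trial):
                            nxt = cand
                            break
                    if nxt is None:
                        break
                    trial.append(nxt)
                if len(trial) == ln:
                    for k, q in enumerate(trial):
                        pos[s + k] = q
                        occupied[tuple(q)] = True
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return LatticeState(L, pos, typ, chain_of, chain_start, chain_len,
                                species_of_chain, np.full(N, -1, dtype=np.int64))
    raise RuntimeError(
        f"failed to place {N} beads on an L={L} lattice after "
        f"{max_restarts} restarts (configuration too dense)")


def total_energy(state: LatticeState, model: InteractionModel,
                 constraint_mode: int = _kernel.C_OFF,
                 T: float = 1.0, T0: float = 1.0,
                 R_B: float = 0.0) -> float:
    """From-scratch total energy: bond + isotropic contact (+ constraint).

    ``constraint_mode`` is one of the kernel constants C_OFF, C_HEAVISIDE,
    C_DELTA; with the constraint active, each bead contributes V(r, T) with
    r its unwrapped distance from the lattice geometric center.
    """
    e = _kernel.interaction_energy(state.pos, state.typ, state.bond, state.occ,
                                   state.L, model.anisotropic_matrix,
                                   model.isotropic_matrix)
    if constraint_mode != _kernel.C_OFF:
        e += _kernel.constraint_energy(state.pos, state.L, constraint_mode,
                                       T, T0, R_B)
    return float(e)


def interaction_energy(state: LatticeState, model: InteractionModel) -> float:
    """Anisotropic + isotropic interaction energy only (no constraint)."""
    return total_energy(state, model)
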