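"""Simulation configuration, annealing schedule, and design-grid helpers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .models import STICKER_INDEX

#: default relative move frequencies (percent): single-bead local
#: displacement, end-bead pivot, chain reptation, whole-chain translation,
#: bond-cluster translation, sticker bond make/break
DEFAULT_MOVE_WEIGHTS = {
    "local": 40.0,
    "pivot": 10.0,
    "reptation": 15.0,
    "chain_translate": 15.0,
    "cluster_translate": 10.0,
    "bond": 10.0,
}

MOVE_ORDER = ("local", "pivot", "reptation", "chain_translate",
              "cluster_translate", "bond")


@dataclass(frozen=True)
class Species:
    """A homopolymer species: every bead carries the same sticker class."""

    name: str
    bead_count: int
    sticker_type: str  # one of "whi3", "rna1", "rna2"
    linker_length: int = 2

    def __post_init__(self):
        if self.bead_count < 1:
            raise ValueError("bead_count must be >= 1")
        if self.sticker_type not in STICKER_INDEX:
            raise ValueError(f"unknown sticker type {self.sticker_type!r}")
        if self.linker_length < 1:
            raise ValueError("linker_length must be >= 1")

    @property
    def span(self) -> int:
        """Maximum end-to-end extent of the chain in lattice units."""
        return (self.bead_count - 1) * self.linker_length


@dataclass
class AnnealingSchedule:
    """Exponential temperature annealing with a central constraining potential.

    The temperature decays as T(t) = T0 + T_EQ * exp(-4 t / t_EQ) toward the
    target T0; once T(t) - T0 falls below ``threshold`` the temperature is
    clamped to T0 and the constraint is switched off.  Two constraint forms
    are supported: ``heaviside_quadratic`` V(r,T) = T H(r - R_B) r^2 (used
    for the three-component runs, with H(0) = 0) and ``delta_quadratic``
    V(r,T) = (T - T0) r^2 (used for the two-component phase-diagram runs).
    r is the Euclidean distance of a bead from the lattice geometric center,
    without periodic wrap.
    """

    T0: float = 1.0
    T_EQ: float = 10.0
    t_EQ: float = 5e7
    threshold: float = 0.005
    constraint_form: str = "heaviside_quadratic"
    R_B: float = 35.0

    def __post_init__(self):
        if self.constraint_form not in ("heaviside_quadratic", "delta_quadratic"):
            raise ValueError(f"unknown constraint form {self.constraint_form!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def clamp_step(self) -> int:
        """First MC step at which T(t) - T0 < threshold (temperature clamped)."""
        # T_EQ * exp(-4 t / t_EQ) < threshold  =>  t > t_EQ/4 * ln(T_EQ/threshold)
        t = self.t_EQ / 4.0 * math.log(self.T_EQ / self.threshold)
        return int(math.floor(t)) + 1


def anneal_temperature(t: float, schedule: AnnealingSchedule) -> float:
    """Temperature at MC step t of the annealing phase.

    Returns exactly T0 once the decay term has dropped below the schedule's
    threshold (the same event at which the constraining potential is
    removed).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    decay = schedule.T_EQ * math.exp(-4.0 * t / schedule.t_EQ)
    if decay < schedule.threshold:
        return schedule.T0
    return schedule.T0 + decay


@dataclass
class SimulationConfig:
    """Full parameterization of one lattice run.

    ``t_EQ`` steps of high-temperature equilibration (anisotropic bonds off,
    constraint on) are followed by ``t_total`` steps of annealing and
    production; samples are taken every ``f_data`` steps, and by default
    only samples from the last half of the production window are kept.
    An MC step is a single elementary move attempt.
    """

    lattice_size: int
    species: list[Species]
    molecule_counts: list[int]
    T_star: float = 1.0
    T_EQ_factor: float = 10.0
    t_EQ: int = 50_000_000
    t_total: int = 10_000_000_000
    f_data: int = 2_500_000
    sample_last_half_only: bool = True
    R_B: float | None = 35.0
    constraint_form: str = "heaviside_quadratic"
    anneal_threshold: float = 0.005
    replicate_count: int = 3
    rng_seed: int = 0
    move_weights: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_WEIGHTS))

    def __post_init__(self):
        if len(self.species) != len(self.molecule_counts):
            raise ValueError("species and molecule_counts must have equal length")
        if any(c <= 0 for c in self.molecule_counts):
            raise ValueError("all molecule counts must be positive")
        max_span = max(sp.span for sp in self.species)
        if self.lattice_size <= 2 * max_span:
            raise ValueError(
                f"lattice_size {self.lattice_size} must exceed twice the maximum "
                f"chain span {max_span}")
        if self.total_beads > self.lattice_size ** 3:
            raise ValueError("total bead count exceeds lattice capacity")
        if self.sample_last_half_only and (self.t_total // 2) % self.f_data != 0:
            raise ValueError("f_data must divide t_total/2")
        unknown = set(self.move_weights) - set(MOVE_ORDER)
        if unknown:
            raise ValueError(f"unknown move types: {sorted(unknown)}")

    @property
    def total_beads(self) -> int:
        return sum(sp.bead_count * n for sp, n in
                   zip(self.species, self.molecule_counts))

    @property
    def T_EQ(self) -> float:
        return self.T_EQ_factor * self.T_star

    def schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(
            T0=self.T_star, T_EQ=self.T_EQ, t_EQ=self.t_EQ,
            threshold=self.anneal_threshold,
            constraint_form=self.constraint_form,
            R_B=self.R_B if self.R_B is not None else 0.0)

    def weight_vector(self) -> np.ndarray:
        w = np.array([self.move_weights.get(m, 0.0) for m in MOVE_ORDER], float)
        if w.sum() <= 0:
            raise ValueError("move weights must not all be zero")
        return w / w.sum()


def sample_schedule(config: SimulationConfig) -> np.ndarray:
    """MC steps (within the production phase) at which samples are taken.

    Samples fall on multiples of ``f_data``; with last-half sampling only
    steps strictly beyond t_total/2 are retained, which yields exactly
    (t_total/2)/f_data samples when f_data divides t_total/2.
    """
    steps = np.arange(config.f_data, config.t_total + 1, config.f_data,
                      dtype=np.int64)
    if config.sample_last_half_only:
        steps = steps[steps > config.t_total // 2]
    return steps


def sample_count(config: SimulationConfig) -> int:
    """Number of samples one replicate will emit (scheduler arithmetic only)."""
    return len(sample_schedule(config))


def two_component_stoichiometries(total_molecules: int,
                                  n_stoichiometries: int) -> list[tuple[int, int]]:
    """Molecule-number pairs (n1, n2), n1 + n2 = total, n1 < n2.

    The pairs are log-spaced in the minority fraction so that both strongly
    asymmetric and near-balanced mixtures are covered; the exactly balanced
    pair is excluded so that the (n1, n2) <-> (n2, n1) swap always produces
    a distinct composition.
    """
    if total_molecules < 2 or n_stoichiometries < 1:
        raise ValueError("counts must be positive")
    fracs = np.geomspace(0.005, 0.45, n_stoichiometries)
    n1 = np.unique(np.maximum(1, np.round(fracs * total_molecules).astype(int)))
    n1 = n1[n1 * 2 < total_molecules]
    # de-duplication can shrink the list on tiny totals; top up linearly
    k = 1
    n1 = set(n1.tolist())
    while len(n1) < n_stoichiometries and k * 2 < total_molecules:
        n1.add(k)
        k += 1
    return [(a, total_molecules - a) for a in sorted(n1)[:n_stoichiometries]]


def enumerate_two_component_grid(total_molecules: int,
                                 n_stoichiometries: int,
                                 box_sizes: list[int],
                                 base_config: SimulationConfig | None = None,
                                 ) -> list[SimulationConfig]:
    """Design grid for two-component phase diagrams.

    For each of ``n_stoichiometries`` molecule-number splits of
    ``total_molecules`` and each box size, both the (n1, n2) and the
    swapped (n2, n1) composition are emitted, giving
    2 * n_stoichiometries * len(box_sizes) configurations (220 for the
    reference design of 22 stoichiometries over five box sizes).
    """
    pairs = two_component_stoichiometries(total_molecules, n_stoichiometries)
    if base_config is None:
        base = SimulationConfig(
            lattice_size=max(box_sizes),
            species=[Species("whi3_mimic", 3, "whi3"),
                     Species("rna_mimic", 8, "rna1")],
            molecule_counts=[1, 1],
            T_EQ_factor=100.0, constraint_form="delta_quadratic", R_B=None,
            t_EQ=50_000_000, t_total=2_000_000_000, f_data=1_000_000,
            replicate_count=2)
    else:
        base = base_config
    configs = []
    for n1, n2 in pairs:
        for L in box_sizes:
            for counts in ((n1, n2), (n2, n1)):
                configs.append(replace(base, lattice_size=L,
                                       molecule_counts=list(counts)))
    return configs
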