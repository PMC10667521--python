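"""Seeded generators for synthetic inputs with planted ground truth.

Each generator is deterministic given its parameters and seed, and returns
(or writes) the planted parameters in a manifest so downstream recoveries
can be scored against ground truth.  The generators emulate the structure
of the real inputs each analysis stage consumes: elliptical binodals with
a planted apparent sticker valence and optional label-flip noise, spot
fields with a planted colocalized fraction, saturating-recovery FRAP
traces, RNA sequence pairs with embedded complementary duplexes, and
desk-scale lattice-simulation presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .boundary import BoundaryDataset
from .config import SimulationConfig, Species
from .imaging import DEFAULT_SPOT_RADIUS_PX, FRAPTraces, SpotField
from .models import InteractionModel, build_interaction_model

_DIAG = np.array([1.0, 1.0]) / math.sqrt(2.0)
_PERP = np.array([1.0, -1.0]) / math.sqrt(2.0)


def gen_phase_boundary(s_star: float,
                       center: float = 40.0,
                       semi_axis_u: float = 30.0,
                       semi_axis_v: float = 12.0,
                       n_points: int = 120,
                       label_noise: float = 0.0,
                       band_halfwidth: float = 0.45,
                       boundary_margin: float = 0.08,
                       arc_halfwidth: float = 1.2,
                       seed: int = 0) -> tuple[BoundaryDataset, dict]:
    """Synthetic binodal with a planted apparent sticker valence.

    The dilute arm derives, in sticker coordinates, from an ellipse
    symmetric about the diagonal: center (c, c), semi-axes ``semi_axis_u``
    along the diagonal and ``semi_axis_v`` across it.  ``n_points``
    concentration points are scattered through an annular band around the
    arm (radial scale factor f uniform in 1 +/- ``band_halfwidth``, polar
    angle within ``arc_halfwidth`` of the point nearest the origin),
    emulating a titration grid that samples well into both regimes rather
    than only hugging the boundary.  Points with f < 1 (inside the arm)
    are two-phase, f > 1 one-phase; a margin of ``boundary_margin`` on
    either side of f = 1 is left unsampled, standing in for the finite
    concentration resolution of a titration series.  Sticker coordinates
    are divided by ``s_star`` on the RNA axis to produce molecule
    concentrations, and labels are flipped with probability
    ``label_noise``.

    Returns (dataset, manifest); the manifest records all planted values.
    """
    if s_star <= 0:
        raise ValueError("planted valence must be positive")
    if not 0 <= boundary_margin < band_halfwidth:
        raise ValueError("boundary_margin must be in [0, band_halfwidth)")
    rng = np.random.default_rng(seed)
    c = center
    lo_f = 1.0 - band_halfwidth
    if c * math.sqrt(2.0) - (1.0 + band_halfwidth) * semi_axis_u < 0 or lo_f <= 0:
        raise ValueError("ellipse band crosses the axes into negative "
                         "concentrations")

    theta = np.pi + arc_halfwidth * (2 * rng.random(n_points) - 1)
    f = 1.0 - band_halfwidth + 2 * band_halfwidth * rng.random(n_points)
    # keep a resolution margin clear of the true boundary
    f = np.where(np.abs(f - 1.0) < boundary_margin,
                 np.where(f < 1.0, 1.0 - boundary_margin, 1.0 + boundary_margin),
                 f)
    u = c * math.sqrt(2.0) + f * semi_axis_u * np.cos(theta)
    v = f * semi_axis_v * np.sin(theta)
    pts = np.outer(u, _DIAG) + np.outer(v, _PERP)
    ok = np.all(pts > 0, axis=1)
    pts, f = pts[ok], f[ok]

    labels = f < 1.0  # inside the arm: two-phase
    flips = rng.random(len(pts)) < label_noise
    labels = labels ^ flips
    pts_mol = pts / np.array([1.0, s_star])
    data = BoundaryDataset(two_phase=pts_mol[labels], one_phase=pts_mol[~labels])
    manifest = {"kind": "boundary", "s_star": float(s_star), "center": float(c),
                "semi_axis_u": float(semi_axis_u),
                "semi_axis_v": float(semi_axis_v),
                "n_points": int(n_points), "label_noise": float(label_noise),
                "band_halfwidth": float(band_halfwidth),
                "boundary_margin": float(boundary_margin),
                "arc_halfwidth": float(arc_halfwidth), "seed": int(seed),
                "n_flipped": int(flips.sum())}
    return data, manifest


def gen_spot_fields(n_ref: int = 200,
                    frac_coloc: float = 0.5,
                    jitter_sd: float = 0.3,
                    field: tuple = (512, 512),
                    density_other: float = 0.0,
                    spot_radius: float = DEFAULT_SPOT_RADIUS_PX,
                    seed: int = 0) -> tuple[SpotField, SpotField, dict]:
    """Two spot fields with a planted colocalized fraction.

    Reference spots are uniform over the field; a fraction ``frac_coloc``
    of them seeds an other-channel spot at the same position plus Gaussian
    jitter (sd below the spot radius), and additional other-channel spots
    are laid down uniformly at ``density_other`` spots per px^2.
    """
    if not 0 <= frac_coloc <= 1:
        raise ValueError("frac_coloc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    W, H = field
    ref = rng.random((n_ref, 2)) * [W, H]
    n_co = int(round(frac_coloc * n_ref))
    chosen = rng.choice(n_ref, size=n_co, replace=False)
    co = ref[chosen] + rng.normal(0.0, jitter_sd, size=(n_co, 2))
    n_bg = rng.poisson(density_other * W * H)
    bg = rng.random((n_bg, 2)) * [W, H]
    other = np.vstack([co, bg]) if (n_co or n_bg) else np.empty((0, 2))
    manifest = {"kind": "spots", "n_ref": n_ref, "frac_coloc": frac_coloc,
                "jitter_sd": jitter_sd, "field": list(field),
                "density_other": density_other, "seed": seed,
                "colocalized_indices": sorted(int(i) for i in chosen)}
    return (SpotField(ref, spot_radius, channel="reference"),
            SpotField(other, spot_radius, channel="other"), manifest)


def gen_frap_traces(plateau: float = 0.2,
                    tau: float = 10.0,
                    noise_sd: float = 0.0,
                    n_acq: int = 3,
                    n_pre: int = 5,
                    n_post: int = 60,
                    dt: float = 3.0,
                    background_level: float = 0.1,
                    seed: int = 0) -> tuple[FRAPTraces, dict]:
    """Saturating-recovery FRAP traces with a planted mobile fraction.

    Pre-bleach intensity is 1 above background; after the bleach the
    bleached-spot signal recovers as plateau * (1 - exp(-t / tau)).  The
    unbleached-condensate and background channels are constant plus noise.
    """
    if not 0 <= plateau <= 1:
        raise ValueError("plateau must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    T = n_pre + n_post
    time = np.arange(T) * dt
    t_post = (np.arange(n_post) + 1) * dt
    signal = np.concatenate([np.ones(n_pre),
                             plateau * (1.0 - np.exp(-t_post / tau))])
    bleached = background_level + signal[None, :] \
        + rng.normal(0, noise_sd, (n_acq, T))
    unbleached = 1.0 + background_level + rng.normal(0, noise_sd, (n_acq, T))
    background = background_level + rng.normal(0, noise_sd, (n_acq, T))
    traces = FRAPTraces(time=time, bleached=bleached, unbleached=unbleached,
                        background=background, pre_bleach_index=n_pre)
    manifest = {"kind": "frap", "plateau": plateau, "tau": tau,
                "noise_sd": noise_sd, "n_acq": n_acq, "n_pre": n_pre,
                "n_post": n_post, "dt": dt, "seed": seed}
    return traces, manifest


_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}  # wobble alternative of the complement


def gen_sequences(length: int = 500,
                  planted_sites: list[tuple[int, int, int]] = (),
                  wobble_fraction: float = 0.0,
                  seed: int = 0) -> tuple[str, str, dict]:
    """Random RNA pair with embedded exact antiparallel duplexes.

    ``planted_sites`` is a list of (site_length, pos1, pos2): the segment
    seq1[pos1 : pos1+site_length] is made perfectly antiparallel-
    complementary to seq2[pos2 : pos2+site_length], using the canonical
    complement, with each eligible position switched to its G-U wobble
    pairing with probability ``wobble_fraction``.  Sites may not overlap.
    """
    rng = np.random.default_rng(seed)
    seq1 = rng.choice(_BASES, size=length)
    seq2 = rng.choice(_BASES, size=length)
    used1, used2 = set(), set()
    for (k, p1, p2) in planted_sites:
        if p1 + k > length or p2 + k > length:
            raise ValueError("planted site does not fit in the sequences")
        r1 = set(range(p1, p1 + k))
        r2 = set(range(p2, p2 + k))
        if (r1 & used1) or (r2 & used2):
            raise ValueError("planted sites overlap")
        used1 |= r1
        used2 |= r2
        for t in range(k):
            b1 = seq1[p1 + t]
            partner = _COMP[b1]
            if b1 in _WOBBLE_PARTNER and rng.random() < wobble_fraction:
                partner = _WOBBLE_PARTNER[b1]
            seq2[p2 + k - 1 - t] = partner
    manifest = {"kind": "sequences", "length": length,
                "planted_sites": [list(map(int, s)) for s in planted_sites],
                "wobble_fraction": wobble_fraction, "seed": seed}
    return "".join(seq1), "".join(seq2), manifest


LATTICE_PRESETS = ("ternary_base", "ternary_hom15", "ternary_rep10",
                   "two_component_grid_small", "boltzmann_toy")


def gen_lattice_toy(preset: str):
    """Desk-scale lattice presets mirroring the reference study designs.

    Returns (config, model).  The ternary presets use a 40-site box with
    200 protein trimers and 40 + 40 RNA-mimic octamers (the full-scale
    design uses L = 100 with 5000/1000/1000 molecules), a scaled
    equilibration of 1e5 steps, 2e6 annealing + production steps, and the
    heaviside central constraint at R_B = 14.  ``boltzmann_toy`` is an
    exactly enumerable two-bead system on a 4-site box used to check the
    sampler against closed-form Boltzmann weights.
    """
    if preset not in LATTICE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {LATTICE_PRESETS}")

    if preset == "boltzmann_toy":
        config = SimulationConfig(
            lattice_size=4,
            species=[Species("a", 1, "whi3"), Species("b", 1, "rna1")],
            molecule_counts=[1, 1],
            t_EQ=1000, t_total=2_000_000, f_data=200,
            T_EQ_factor=1.0, R_B=None, constraint_form="heaviside_quadratic",
            replicate_count=1,
            move_weights={"local": 0.5, "bond": 0.3, "cluster_translate": 0.2})
        aniso = np.zeros((3, 3))
        aniso[0, 1] = aniso[1, 0] = -2.0
        iso = np.zeros((3, 3))
        iso[0, 1] = iso[1, 0] = 0.3
        model = InteractionModel(aniso, iso, name="boltzmann_toy")
        return config, model

    if preset == "two_component_grid_small":
        config = SimulationConfig(
            lattice_size=30,
            species=[Species("whi3_mimic", 3, "whi3"),
                     Species("rna_mimic", 8, "rna1")],
            molecule_counts=[80, 30],
            T_EQ_factor=100.0, constraint_form="delta_quadratic", R_B=0.0,
            t_EQ=100_000, t_total=2_000_000, f_data=25_000,
            replicate_count=2)
        return config, build_interaction_model("base")

    config = SimulationConfig(
        lattice_size=40,
        species=[Species("whi3", 3, "whi3"),
                 Species("rna1", 8, "rna1"),
                 Species("rna2", 8, "rna2")],
        molecule_counts=[200, 40, 40],
        T_EQ_factor=10.0, constraint_form="heaviside_quadratic", R_B=14.0,
        t_EQ=100_000, t_total=2_000_000, f_data=25_000,
        replicate_count=3)
    if preset == "ternary_base":
        model = build_interaction_model("base")
    elif preset == "ternary_hom15":
        model = build_interaction_model("hom_scaling", 1.5)
    else:  # ternary_rep10
        model = build_interaction_model("iso_repulsion", 10.0)
    return config, model
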