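"""Sticker interaction models for the lattice polymer simulations.

Three sticker classes are distinguished: the protein (Whi3 mimic) sticker
and two RNA-mimic stickers.  Interactions are split into an *anisotropic*
part, realized as explicit saturable one-to-one bonds between stickers, and
an *isotropic* contact part evaluated over every pair of beads within the
contact radius (the 26-site neighborhood, i.e. a radius of sqrt(3) lattice
units).  All energies are in units of k_B*T*, with the reference temperature
T* = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: base heterotypic sticker energy, k_B T*
EPSILON = -2.0
#: base isotropic repulsion between unlike RNA mimics, k_B T* (~1/26)
EPSILON_REP = 0.04
#: index of each sticker class in the 3x3 matrices
STICKER_INDEX = {"whi3": 0, "rna1": 1, "rna2": 2}

MODEL_NAMES = ("base", "hom_scaling", "asymm", "iso_repulsion")


@dataclass
class InteractionModel:
    """3x3 anisotropic (bond) and isotropic (contact) energy matrices.

    Rows/columns follow :data:`STICKER_INDEX`: protein sticker, RNA1
    sticker, RNA2 sticker.  Both matrices must be symmetric.
    """

    anisotropic_matrix: np.ndarray
    isotropic_matrix: np.ndarray
    name: str = "custom"
    epsilon: float = EPSILON
    epsilon_rep: float = EPSILON_REP
    scale_h: float = 0.0
    scale_a: float = 1.0
    scale_s: float = 0.0
    contact_radius: float = math.sqrt(3.0)

    def __post_init__(self) -> None:
        self.anisotropic_matrix = np.asarray(self.anisotropic_matrix, dtype=float)
        self.isotropic_matrix = np.asarray(self.isotropic_matrix, dtype=float)
        for m, label in ((self.anisotropic_matrix, "anisotropic"),
                         (self.isotropic_matrix, "isotropic")):
            if m.shape != (3, 3):
                raise ValueError(f"{label} matrix must be 3x3, got {m.shape}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{label} matrix must be symmetric")


def build_interaction_model(name: str, scale: float | None = None) -> InteractionModel:
    """Construct one of the named interaction models.

    Parameters
    ----------
    name:
        One of ``base``, ``hom_scaling`` (scale = h, homotypic RNA-RNA
        sticker energy h*epsilon), ``asymm`` (scale = a, protein-RNA1
        sticker energy a*epsilon), ``iso_repulsion`` (scale = s, isotropic
        RNA1-RNA2 contact energy s*epsilon_rep).
    scale:
        The dimensionless scaling factor h, a or s.  Defaults: h=0, a=1,
        s=1, each of which is listed in the model's reference scale set.

    Notes
    -----
    ``hom_scaling`` with h=0 and ``asymm`` with a=1 reduce exactly to the
    base case.  h and a must be non-negative: the attractive sign lives in
    epsilon itself, so a negative scale almost certainly indicates a
    sign-flip misuse.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown interaction model {name!r}; choose from {MODEL_NAMES}")

    aniso = np.zeros((3, 3))
    iso = np.zeros((3, 3))
    # heterotypic protein-RNA sticker attractions common to all models
    aniso[0, 1] = aniso[1, 0] = EPSILON
    aniso[0, 2] = aniso[2, 0] = EPSILON

    h, a, s = 0.0, 1.0, 0.0
    if name == "hom_scaling":
        h = 0.0 if scale is None else float(scale)
        if h < 0:
            raise ValueError("homotypic scaling factor h must be non-negative")
        aniso[1, 1] = aniso[2, 2] = h * EPSILON
    elif name == "asymm":
        a = 1.0 if scale is None else float(scale)
        if a < 0:
            raise ValueError("asymmetry scaling factor a must be non-negative")
        aniso[0, 1] = aniso[1, 0] = a * EPSILON
    elif name == "iso_repulsion":
        s = 1.0 if scale is None else float(scale)
        iso[1, 2] = iso[2, 1] = s * EPSILON_REP

    return InteractionModel(aniso, iso, name=name, scale_h=h, scale_a=a, scale_s=s)
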