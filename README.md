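# condmix

Lattice sticker-spacer simulations and demixing analysis for protein-RNA
condensates.

Biomolecular condensates formed by an RNA-binding protein (such as Whi3 of
*Ashbya gossypii*) together with its target mRNAs (*CLN3*, *BNI1*, *SPA2*)
can retain compositional identity — two condensate types coexisting in the
same cytoplasm without merging — even though every component interacts
with every other.  `condmix` implements the computational machinery for
studying how such demixing arises, for computational biophysicists and
quantitative cell biologists:

* **Lattice Monte Carlo engine** (`condmix.lattice`, `condmix.simulate`):
  sticker-spacer polymers on a periodic cubic lattice.  The protein mimic
  is a 3-sticker trimer (W3), the RNA mimics are 8-sticker octamers (A8,
  B8) with implicit two-site linkers.  Sticker interactions are explicit,
  saturable one-to-one bonds drawn from a 3x3 anisotropic energy matrix
  (base heterotypic energy eps = -2 k_BT*), optionally supplemented by an
  isotropic contact matrix (e.g. an RNA1-RNA2 contact repulsion
  s*eps_rep with eps_rep = 0.04 k_BT*).  The production protocol
  equilibrates at high temperature under a central constraining potential,
  anneals exponentially, T(t) = T0 + T_EQ exp(-4t/t_EQ), and samples the
  last half of the run.
* **Demixing quantification** (`condmix.density`): radial density
  profiles rho(r_n) = H(r_n)/H0(r_n) about the system or largest-cluster
  center of mass, with the lattice-site histogram H0 enumerated exactly;
  coexisting dense/dilute densities from fixed radial windows; and the
  Hellinger-distance demixing score

      D_ij = sqrt(1 - sum_n sqrt(rho~_ii(r_n) rho~_ij(r_n)))

  which is 0 for a well-mixed pair of components and 1 for fully demixed
  ones.
* **Apparent sticker valence from binodals** (`condmix.boundary`): if
  heterotypic sticker interactions dominate, a measured phase boundary
  becomes symmetric about the diagonal when the RNA axis is rescaled from
  molecule to sticker concentrations.  The scan finds the scaling factor
  s (the RNA's apparent sticker valence, with the protein fixed at
  valence 1) that minimizes the overlap between the one-phase region and
  the mirrored two-phase arm, reports the band of s within 5% of the
  minimum, fits a guaranteed ellipse (direct constrained least squares
  that can never return a hyperbola) to the symmetrized boundary, and
  derives non-cognate:cognate sticker ratios
  (valence - cognate)/cognate.
* **Imaging quantification** (`condmix.imaging`): smFISH spot
  colocalization (a reference spot counts as colocalized when another
  channel's center lies strictly within 2r, r = 1.389 px = 150 nm), the
  pixel-shift chance-coincidence control, nuclear proximity splits using
  R = sqrt(A/pi) from segmented nucleus areas, pixel-wise Pearson
  correlation between channels, and FRAP trace processing (5% unbleached
  drift QC, background subtraction, normalization to the maximum of the
  averaged trace).
* **RNA-RNA complementarity** (`condmix.rna`): maximal antiparallel
  duplexes of length >= 11 under Watson-Crick plus G-U wobble pairing,
  with mean per-nucleotide reactivity over matched sites.
* **Synthetic data** (`condmix.synth`): seeded generators with planted
  ground truth for every stage — elliptical binodals with a planted
  valence and label noise, spot fields with a planted colocalized
  fraction, saturating FRAP traces, sequence pairs with embedded
  duplexes, and desk-scale simulation presets.

## Worked example: extracting an apparent sticker valence

```python
import numpy as np
from condmix import (gen_phase_boundary, scan_apparent_valence,
                     remap_to_sticker_concentrations, fit_guaranteed_ellipse,
                     noncognate_ratio)

# synthetic titration of a Whi3-like protein against an RNA whose planted
# apparent valence is 133, with 5% of phase labels flipped
data, truth = gen_phase_boundary(s_star=133.0, label_noise=0.05, seed=7)

scan = scan_apparent_valence(data)
print(f"apparent sticker valence s* = {scan.s_star:.1f}")
print(f"5%-band: {scan.band[0]:.1f} - {scan.band[1]:.1f}")

remapped = remap_to_sticker_concentrations(data, scan.s_star)
pts = np.vstack([remapped.two_phase, remapped.two_phase[:, ::-1]])
fit = fit_guaranteed_ellipse(pts)
print(f"ellipse fit: semi-axes=({fit.semi_axes[0]:.1f}, "
      f"{fit.semi_axes[1]:.1f}), R^2={fit.r_squared:.3f}")
print(f"non-cognate:cognate ratio at 5 cognate sites: "
      f"{noncognate_ratio(scan.s_star, 5):.1f}")
```

Output:

```
apparent sticker valence s* = 132.2
5%-band: 121.7 - 144.0
ellipse fit: semi-axes=(8.1, 7.7), R^2=0.835
non-cognate:cognate ratio at 5 cognate sites: 25.4
```

The scan recovers the planted valence within 1%, the 5% band brackets it,
the symmetrized boundary is nearly circular (axes 8.1 vs 7.7 in sticker
units), and the derived non-cognate:cognate ratio lands next to the 25.6
expected for a valence-133 RNA with five cognate UGCAU motifs.

## Command line

A `condmix` entry point wraps each stage: `simulate`, `grid`, `profile`,
`demix`, `valence`, `ellipse`, `tieline`, `coloc-spots`, `coloc-pixels`,
`frap`, `sites` and `synth`.  For instance:

```sh
condmix synth boundary --seed 7 -p s_star=133 -p label_noise=0.05 --out b.csv
condmix valence --boundary b.csv --out valence.json
```

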