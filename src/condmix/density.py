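"""Radial density profiles, coexisting densities, and the demixing score.

Profiles are occupancy fractions: a bead-count histogram H(r_n) about a
chosen center (system center of mass, or the center of mass of the largest
cluster of a component), divided bin-by-bin by the exactly enumerated
site-count histogram H0(r_n) of the periodic lattice, with bin width 0.25
lattice units from r = 0 to sqrt(3) L / 2.  Demixing between two
components is scored by the Hellinger distance between their normalized
radial profiles about the same center:

    D = sqrt(1 - BC),   BC = sum_n sqrt(rho~_ii(r_n) * rho~_ij(r_n)),

where each rho~ is the profile normalized to unit sum over its defined
bins.  D is 0 for identical profiles (well-mixed) and 1 for disjoint ones
(fully demixed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

DEFAULT_BIN_WIDTH = 0.25
CONTACT_RADIUS = np.sqrt(3.0)


def bin_edges(L: int, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    r_max = np.sqrt(3.0) * L / 2.0
    n_bins = int(np.ceil(r_max / bin_width))
    return np.arange(n_bins + 1) * bin_width


def _min_image_dist(points: np.ndarray, center: np.ndarray, L: int) -> np.ndarray:
    d = np.abs(points - np.asarray(center, float))
    d = np.minimum(d, L - d)
    return np.sqrt((d ** 2).sum(axis=1))


@lru_cache(maxsize=32)
def _site_histogram_cached(L: int, center_key: tuple, bin_width: float) -> np.ndarray:
    center = np.array(center_key, float)
    ax = np.arange(L)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    sites = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1).astype(float)
    r = _min_image_dist(sites, center, L)
    edges = bin_edges(L, bin_width)
    H0, _ = np.histogram(r, bins=edges)
    return H0


def site_histogram(L: int, center, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """H0(r_n): explicit count of lattice sites per radial bin.

    Enumerates all L^3 sites at their minimum-image distance from the
    (possibly fractional) center; sums to L^3 exactly.
    """
    key = tuple(round(float(c), 6) for c in center)
    return _site_histogram_cached(int(L), key, float(bin_width))


@dataclass
class DensityProfile:
    """rho(r_n) = H(r_n) / H0(r_n); NaN where H0 = 0."""

    rho: np.ndarray
    counts: np.ndarray
    site_counts: np.ndarray
    edges: np.ndarray
    center: np.ndarray
    L: int
    component: str = ""
    reference: str = "system"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def defined(self) -> np.ndarray:
        return self.site_counts > 0


def radial_density_profile(positions: np.ndarray, center, L: int,
                           bin_width: float = DEFAULT_BIN_WIDTH,
                           component: str = "",
                           reference: str = "system") -> DensityProfile:
    """Radial occupancy-fraction profile of a set of bead positions.

    Distances are computed under the minimum-image convention; the center
    may be fractional (a center of mass).  An empty position set yields an
    all-zero profile.
    """
    center = np.asarray(center, float)
    if np.any(center < 0) or np.any(center >= L):
        raise ValueError("center must lie within the lattice")
    edges = bin_edges(L, bin_width)
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(positions) == 0:
        import warnings
        warnings.warn("empty component: all-zero density profile")
        H = np.zeros(len(edges) - 1)
    else:
        r = _min_image_dist(positions, center, L)
        H, _ = np.histogram(r, bins=edges)
    H0 = site_histogram(L, center, bin_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(H0 > 0, H / np.maximum(H0, 1), np.nan)
    return DensityProfile(rho=rho, counts=H.astype(float),
                          site_counts=H0.astype(float), edges=edges,
                          center=center, L=L, component=component,
                          reference=reference)


def system_com(positions: np.ndarray, L: int) -> np.ndarray:
    """Periodic-aware center of mass via the per-axis circular mean.

    Suitable for arbitrary (possibly box-spanning) bead sets; for compact
    clusters :func:`cluster_com` is exact and preferred.
    """
    theta = np.asarray(positions, float) * (2 * np.pi / L)
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0),
                            np.cos(theta).mean(axis=0))
    return (mean_angle * L / (2 * np.pi)) % L


def cluster_com(positions: np.ndarray, L: int) -> np.ndarray:
    """Exact periodic COM of a compact cluster (diameter < L/2).

    Unwraps every bead by its minimum-image displacement from the first
    bead, averages, and wraps back; agrees exactly with the arithmetic
    mean whenever the cluster does not straddle a boundary.
    """
    pts = np.asarray(positions, float).reshape(-1, 3)
    ref = pts[0]
    d = (pts - ref + L / 2.0) % L - L / 2.0
    return (ref + d.mean(axis=0)) % L


def largest_cluster_com(positions: np.ndarray, L: int,
                        contact_d2: float = 3.0) -> np.ndarray:
    """COM of the largest contact-radius-connected cluster of the beads.

    Connectivity uses the 26-site neighborhood (squared distance <= 3,
    matching the interaction range).  Equal-sized clusters tie-break to the
    one containing the lowest bead index.  The COM is periodic-aware and
    exact for clusters of diameter below L/2 (see :func:`cluster_com`).
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    if len(positions) == 0:
        raise ValueError("component has no beads")
    tree = cKDTree(positions % L, boxsize=L)
    pairs = tree.query_pairs(np.sqrt(contact_d2) + 1e-9, output_type="ndarray")
    n = len(positions)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:  # tie: cluster holding the lowest bead index
        first_idx = np.array([np.flatnonzero(labels == c)[0] for c in best])
        best = [best[np.argmin(first_idx)]]
    return cluster_com(positions[labels == best[0]], L)


@dataclass
class CoexistencePoint:
    """Dense- and dilute-phase occupancy fractions from one profile."""

    dense: float
    dilute: float
    dense_window: tuple
    dilute_window: tuple


def coexisting_densities(profile: DensityProfile,
                         dense_bins: int = 13,
                         dilute_bins: int = 20,
                         tail_skip: int = 15) -> CoexistencePoint:
    """Average rho over the dense and dilute windows of a radial profile.

    Dense phase: mean over the first ``dense_bins`` bins; dilute phase:
    mean over ``dilute_bins`` bins ending ``tail_skip`` bins before the
    last bin (near the end of the box but avoiding the corner bins).
    Bins with no lattice sites (H0 = 0) are excluded from the means.
    """
    n = len(profile.rho)
    if n < dense_bins + dilute_bins + tail_skip:
        raise ValueError(
            f"profile has {n} bins; needs >= {dense_bins + dilute_bins + tail_skip}")
    lo, hi = n - tail_skip - dilute_bins, n - tail_skip
    dense = float(np.nanmean(profile.rho[:dense_bins]))
    dilute = float(np.nanmean(profile.rho[lo:hi]))
    return CoexistencePoint(dense=dense, dilute=dilute,
                            dense_window=(0, dense_bins),
                            dilute_window=(lo, hi))


@dataclass
class DemixingScore:
    """Hellinger-distance demixing measure for a component pair."""

    D: float
    bhattacharyya: float
    pair: tuple = ("", "")


def _normalize(rho: np.ndarray, defined: np.ndarray) -> np.ndarray:
    v = np.where(defined, rho, 0.0)
    total = v.sum()
    if total <= 0:
        raise ValueError("zero-mass profile cannot be normalized")
    return v / total


def demixing_measure(profile_ii: DensityProfile | np.ndarray,
                     profile_ij: DensityProfile | np.ndarray,
                     pair: tuple = ("", "")) -> DemixingScore:
    """Hellinger distance between two normalized radial profiles.

    Accepts DensityProfile objects (bins with H0 = 0 are dropped from the
    normalization sums) or bare non-negative histogram arrays of equal
    length.  Returns D in [0, 1] and the Bhattacharyya coefficient.
    """
    if isinstance(profile_ii, DensityProfile):
        if len(profile_ii.rho) != len(profile_ij.rho):
            raise ValueError("profiles must share binning")
        defined = profile_ii.defined & profile_ij.defined
        p = _normalize(np.nan_to_num(profile_ii.rho), defined)
        q = _normalize(np.nan_to_num(profile_ij.rho), defined)
    else:
        p = np.asarray(profile_ii, float)
        q = np.asarray(profile_ij, float)
        if p.shape != q.shape:
            raise ValueError("profiles must share binning")
        if np.any(p < 0) or np.any(q < 0):
            raise ValueError("profiles must be non-negative")
        p = _normalize(p, np.ones_like(p, bool))
        q = _normalize(q, np.ones_like(q, bool))
    bc = float(np.sqrt(p * q).sum())
    bc = min(bc, 1.0)
    return DemixingScore(D=float(np.sqrt(1.0 - bc)), bhattacharyya=bc, pair=pair)


def mean_profiles_and_demixing(samples, config, model_component_i: str,
                               model_component_j: str,
                               reference: str = "cluster"):
    """Average per-sample profiles about component i's cluster COM, then D_ij.

    ``samples`` is a list of TrajectorySample; components are species
    names from the config.  With reference="cluster" the center for each
    sample is the COM of the largest cluster of component i; with
    "system" it is the full-system COM.  Profiles are averaged across
    samples before the Hellinger distance is computed (per-sample scores
    can be obtained by passing a single-sample list).
    """
    L = config.lattice_size
    name_to_slice = {}
    b = 0
    for sp, n_mol in zip(config.species, config.molecule_counts):
        nb = sp.bead_count * n_mol
        name_to_slice[sp.name] = slice(b, b + nb)
        b += nb
    sl_i = name_to_slice[model_component_i]
    sl_j = name_to_slice[model_component_j]
    acc_ii, acc_ij = None, None
    for s in samples:
        pos_i = s.positions[sl_i]
        pos_j = s.positions[sl_j]
        if reference == "cluster":
            center = largest_cluster_com(pos_i, L)
        else:
            center = system_com(s.positions, L)
        pi = radial_density_profile(pos_i, center, L,
                                    component=model_component_i)
        pj = radial_density_profile(pos_j, center, L,
                                    component=model_component_j)
        if acc_ii is None:
            acc_ii = np.zeros_like(pi.rho)
            acc_ij = np.zeros_like(pj.rho)
            site_counts = pi.site_counts
            edges = pi.edges
        acc_ii += np.nan_to_num(pi.rho)
        acc_ij += np.nan_to_num(pj.rho)
    n = len(samples)
    mean_ii = DensityProfile(acc_ii / n, acc_ii, site_counts, edges,
                             np.zeros(3), L, model_component_i, reference)
    mean_ij = DensityProfile(acc_ij / n, acc_ij, site_counts, edges,
                             np.zeros(3), L, model_component_j, reference)
    return mean_ii, mean_ij, demixing_measure(
        mean_ii, mean_ij, pair=(model_component_i, model_component_j))
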