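"""Phase-boundary analysis: symmetrization, apparent sticker valence,
guaranteed ellipse fitting, and tie lines.

A two-component phase diagram is summarized by labeled concentration
points: ``P`` points along the lower boundary of the two-phase regime and
``N`` points along the upper boundary of the one-phase regime.  If phase
separation is dominated by heterotypic sticker interactions, recasting the
RNA axis in sticker concentrations (multiplying by a valence scaling
factor s, with the protein sticker valence fixed at 1) should make the
dilute arm symmetric about the diagonal.  The apparent sticker valence is
the s that minimizes the overlap between the region traced by the N
points and the region traced by the P points plus their diagonal mirror;
the reported uncertainty band contains every s whose overlap area is
within 5% of the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import MultiPoint, Point, Polygon

__all__ = [
    "BoundaryDataset", "ValenceScan", "EllipseFit", "TieLine",
    "remap_to_sticker_concentrations", "overlap_area",
    "scan_apparent_valence", "fit_guaranteed_ellipse", "noncognate_ratio",
    "tie_line",
]


@dataclass
class BoundaryDataset:
    """Labeled one-/two-phase concentration points.

    x is the protein axis, y the RNA axis; units are carried as metadata
    ("uM" for in vitro data, "sticker" after remapping) and mixing them in
    one operation raises.
    """

    two_phase: np.ndarray  # (n, 2)
    one_phase: np.ndarray  # (m, 2)
    units: str = "uM"

    def __post_init__(self):
        self.two_phase = np.atleast_2d(np.asarray(self.two_phase, float))
        self.one_phase = np.atleast_2d(np.asarray(self.one_phase, float))
        for arr, lab in ((self.two_phase, "two_phase"),
                         (self.one_phase, "one_phase")):
            if arr.shape[1] != 2:
                raise ValueError(f"{lab} must be (n, 2)")
            if np.any(arr < 0):
                raise ValueError(f"{lab} contains negative concentrations")


def remap_to_sticker_concentrations(data: BoundaryDataset, s: float,
                                    protein_valence: float = 1.0
                                    ) -> BoundaryDataset:
    """Rescale the RNA axis by the valence factor s (protein valence fixed).

    With ``protein_valence`` != 1 the x axis is scaled too (useful for
    simulation mimics with known sticker counts per molecule).
    """
    if s <= 0:
        raise ValueError("valence scaling factor s must be positive")
    scale = np.array([protein_valence, s])
    return BoundaryDataset(data.two_phase * scale, data.one_phase * scale,
                           units="sticker")


def _region(points: np.ndarray, polygon_method: str, concave_ratio: float):
    """Boundary polygon of one point cloud, traced in a standardized frame.

    Hull shapes are not invariant under anisotropic axis rescaling, so the
    cloud is first mapped to a frame where both axes span comparable
    ranges, shrink-wrapped (or convex-hulled) there, and the polygon's
    vertices mapped back.
    """
    points = np.asarray(points, float)
    if len(points) < 3:
        raise ValueError("need at least 3 points per phase label")
    sc = points.max(axis=0)
    sc[sc <= 0] = 1.0
    mp = MultiPoint([tuple(p) for p in points / sc])
    if polygon_method == "convex":
        poly = mp.convex_hull
    elif polygon_method == "concave":
        poly = shapely.concave_hull(mp, ratio=concave_ratio)
    else:
        raise ValueError(f"unknown polygon method {polygon_method!r}")
    if poly.geom_type != "Polygon" or not poly.is_valid:
        raise ValueError("degenerate point set: cannot form a polygon")
    return affinity.scale(poly, xfact=sc[0], yfact=sc[1], origin=(0, 0))


_SWAP_XY = [0, 1, 1, 0, 0, 0]  # shapely affine coefficients for (x,y)->(y,x)


def _symmetry_bridge(hull_P_log, s: float):
    """Symmetrized two-phase region at valence scaling s, in log space.

    In log-concentration coordinates the RNA-axis rescaling is a rigid
    vertical translation by log s and the diagonal mirror is a rigid
    reflection, so the two-phase hull is built once and only moved
    rigidly — nothing degenerates anywhere on a many-decade scan grid.
    The region is the convex hull of the translated arm together with its
    mirror image: it collapses onto the arm when the arm is
    diagonal-symmetric about the diagonal and fills the lens between arm
    and mirror when it is not.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    ls = float(np.log(s))
    Pt = affinity.translate(hull_P_log, 0.0, ls)
    Pm = affinity.affine_transform(Pt, _SWAP_XY)
    return Pt.union(Pm).convex_hull


def one_phase_coverage(data: BoundaryDataset, s: float) -> float:
    """Fraction of one-phase points covered by the symmetrized two-phase
    region at valence scaling s.

    This is the scan objective: a sampling-measure estimate of the
    fractional overlap between the one-phase regime and the mirrored
    two-phase regime.  Counting points instead of intersecting polygon
    areas makes the objective robust — a single mislabeled point changes
    the value by at most 1/m and cannot displace the location of the
    minimum.
    """
    if np.any(data.two_phase <= 0) or np.any(data.one_phase <= 0):
        raise ValueError("log-space analysis requires strictly positive "
                         "concentrations")
    hull_P = MultiPoint([tuple(p) for p in np.log(data.two_phase)]).convex_hull
    bridge = _symmetry_bridge(hull_P, s)
    N = np.log(data.one_phase) + [0.0, np.log(s)]
    return float(shapely.contains_xy(bridge, N[:, 0], N[:, 1]).mean())


def prune_inconsistent_labels(data: BoundaryDataset, k: int = 7,
                              vote: float = 0.7,
                              concave_ratio: float = 0.3) -> BoundaryDataset:
    """Drop points whose phase label contradicts the surrounding data.

    Two complementary filters run in log-concentration coordinates (where
    distances are scale-free).  A point is removed when (a) at least a
    ``vote`` supermajority of its k nearest neighbors carry the opposite
    label, or (b) it lies strictly inside the concave region traced by
    the opposite class.  Under symmetric label-flip noise the flipped
    points sit deep inside the opposite regime — near-unanimous opposite
    neighborhoods catch interior flips, and region containment catches
    flips near the sparse ends of the sampled boundary arm where
    neighborhoods are ambiguous.  Honest points near the phase boundary
    see a mixed neighborhood and lie outside the opposite region, so
    clean, well-separated data pass through unchanged.  The pruning is
    skipped if it would leave fewer than 3 points in either class.
    """
    from scipy.spatial import cKDTree
    pts = np.vstack([data.two_phase, data.one_phase])
    lab = np.r_[np.ones(len(data.two_phase), bool),
                np.zeros(len(data.one_phase), bool)]
    if len(pts) <= k or np.any(pts <= 0):
        return data
    z = np.log(pts)
    tree = cKDTree(z)
    _, idx = tree.query(z, k=k + 1)
    frac_opposite = (lab[idx[:, 1:]] != lab[:, None]).mean(axis=1)
    keep = frac_opposite < vote
    try:
        hull_P = shapely.concave_hull(
            MultiPoint([tuple(p) for p in z[lab]]), ratio=concave_ratio)
        hull_N = shapely.concave_hull(
            MultiPoint([tuple(p) for p in z[~lab]]), ratio=concave_ratio)
        in_P = shapely.contains_xy(hull_P, z[:, 0], z[:, 1])
        in_N = shapely.contains_xy(hull_N, z[:, 0], z[:, 1])
        keep &= ~np.where(lab, in_N, in_P)
    except shapely.errors.GEOSException:  # degenerate cloud: skip filter (b)
        pass
    if keep[lab].sum() < 3 or keep[~lab].sum() < 3:
        return data
    return BoundaryDataset(pts[keep & lab], pts[keep & ~lab],
                           units=data.units)


def overlap_area(data: BoundaryDataset, s: float,
                 polygon_method: str = "concave",
                 concave_ratio: float = 0.3) -> float:
    """Overlap area between the one-phase region and the symmetrized arm.

    Builds a polygon over the rescaled one-phase points (x_N, s*y_N) and
    one over the rescaled two-phase points together with their diagonal
    mirror ([x_P, s*y_P] union [s*y_P, x_P]); returns the area of their
    intersection, on linear concentration axes.  The default boundary
    tracing is a shrink-wrapped (concave) hull; ``polygon_method="convex"``
    selects convex hulls.  (The valence scan minimizes the log-space
    variant computed by :func:`scan_apparent_valence`, which is better
    behaved over a many-decade grid; this linear-space area matches the
    source construction and is exposed for direct use.)
    """
    scaled = BoundaryDataset(data.two_phase * np.array([1.0, s]),
                             data.one_phase * np.array([1.0, s]),
                             units=data.units)
    P = scaled.two_phase
    poly_N = _region(scaled.one_phase, polygon_method, concave_ratio)
    poly_P = _region(np.vstack([P, P[:, ::-1]]), polygon_method, concave_ratio)
    return float(poly_N.intersection(poly_P).area)


@dataclass
class ValenceScan:
    """Result of the apparent-sticker-valence scan."""

    s_grid: np.ndarray
    areas: np.ndarray
    s_star: float
    band: tuple  # (s_low, s_high): all s with area <= 1.05 * min
    band_members: np.ndarray
    flat: bool = False


def scan_apparent_valence(data: BoundaryDataset,
                          s_grid: np.ndarray | None = None,
                          polygon_method: str = "concave",
                          concave_ratio: float = 0.3,
                          band_factor: float = 1.05,
                          refine: bool = True,
                          prune: bool = True) -> ValenceScan:
    """Scan s over a grid, minimize the symmetrization-overlap objective.

    The default grid is 200 log-spaced values over [1e-1, 1e4]; the grid
    is refined once (about 10x finer) across the coarse argmin region —
    the objective typically bottoms out on a plateau of (near-)zero
    coverage, and the whole plateau is refined.  The reported s_star is
    the geometric center of the argmin set (the argmin itself when the
    minimum is unique); the band holds every evaluated s whose objective
    is within ``band_factor`` (5% by default) of the minimum.  A flat
    objective is flagged and yields no unique s.

    The objective (see :func:`one_phase_coverage`) is the fraction of
    one-phase points covered by the symmetrized two-phase region,
    evaluated in log-concentration coordinates where the s-rescaling and
    the diagonal mirror act as rigid motions on a hull traced once from
    the data: smooth in s, free of polygon degeneracies over a
    many-decade grid, and robust to individual outliers.  ``prune``
    applies :func:`prune_inconsistent_labels` first (recommended for
    measured or label-noisy data; a no-op on clean, well-separated data).
    ``polygon_method``/``concave_ratio`` control the boundary tracing
    used by the pruning step.
    """
    if s_grid is None:
        s_grid = np.geomspace(1e-1, 1e4, 200)
    s_grid = np.asarray(s_grid, float)
    if np.any(s_grid <= 0) or np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be positive and strictly increasing")
    if prune:
        data = prune_inconsistent_labels(data, concave_ratio=concave_ratio)
    if np.any(data.two_phase <= 0) or np.any(data.one_phase <= 0):
        raise ValueError("log-space analysis requires strictly positive "
                         "concentrations")
    if len(data.two_phase) < 3 or len(data.one_phase) < 3:
        raise ValueError("need at least 3 points per phase label")
    hull_P = MultiPoint([tuple(p) for p in np.log(data.two_phase)]).convex_hull
    N_log = np.log(data.one_phase)

    def _areas(grid):
        out = np.empty(len(grid))
        for k, s in enumerate(grid):
            bridge = _symmetry_bridge(hull_P, s)
            Nt = N_log + [0.0, np.log(s)]
            out[k] = shapely.contains_xy(bridge, Nt[:, 0], Nt[:, 1]).mean()
        return out

    areas = _areas(s_grid)
    grid_all, areas_all = s_grid, areas
    if refine and len(s_grid) > 2:
        a_min = areas.min()
        tol = a_min + 1e-12 + 1e-9 * abs(a_min)
        low_set = np.flatnonzero(areas <= tol)
        lo = s_grid[max(low_set[0] - 1, 0)]
        hi = s_grid[min(low_set[-1] + 1, len(s_grid) - 1)]
        fine = np.geomspace(lo, hi, 41)
        fine_areas = _areas(fine)
        grid_all = np.concatenate([s_grid, fine])
        areas_all = np.concatenate([areas, fine_areas])
        order = np.argsort(grid_all)
        grid_all, areas_all = grid_all[order], areas_all[order]

    flat = bool(np.ptp(areas_all) < 1e-12 * max(1.0, areas_all.max()))
    a_min = areas_all.min()
    winners = grid_all[areas_all <= a_min + 1e-12 + 1e-9 * abs(a_min)]
    # the objective bottoms out on a plateau when the symmetrized arm
    # clears the one-phase region over a range of s; the symmetric point
    # estimate is the plateau's geometric center (identical to the argmin
    # when the minimum is unique)
    s_star = float(np.exp(np.log(winners).mean()))
    members = grid_all[areas_all <= band_factor * a_min + 1e-15]
    return ValenceScan(s_grid=grid_all, areas=areas_all, s_star=s_star,
                       band=(float(members.min()), float(members.max())),
                       band_members=members, flat=flat)


@dataclass
class EllipseFit:
    """Conic-section fit constrained to be an ellipse."""

    conic: np.ndarray            # (a, b, c, d, e, f): ax^2+bxy+cy^2+dx+ey+f=0
    center: tuple
    semi_axes: tuple             # (major, minor)
    orientation: float           # radians, major axis vs +x
    r_squared: float             # 1 - SS_res/SS_tot, geometric residuals
    r_squared_algebraic: float   # same with normalized algebraic residuals


def fit_guaranteed_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    Uses the numerically stable formulation of the direct ellipse-specific
    least-squares method (constraint 4ac - b^2 = 1), which cannot return a
    hyperbola or parabola regardless of noise.  The goodness of fit is
    reported as R^2 = 1 - SS_res/SS_tot with orthogonal (geometric)
    point-to-ellipse residuals and SS_tot the squared scatter of the points
    about their centroid; an algebraic-residual variant is also reported.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points to fit an ellipse")
    x, y = pts[:, 0], pts[:, 1]
    if np.linalg.matrix_rank(np.column_stack([x - x.mean(), y - y.mean()])) < 2:
        raise ValueError("collinear points cannot define an ellipse")
    # center and scale for conditioning
    mx, my = x.mean(), y.mean()
    sc = max(np.abs(x - mx).max(), np.abs(y - my).max(), 1e-12)
    u, v = (x - mx) / sc, (y - my) / sc

    D1 = np.column_stack([u * u, u * v, v * v])
    D2 = np.column_stack([u, v, np.ones_like(u)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    Tm = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ Tm
    C1inv = np.array([[0, 0, 0.5], [0, -1, 0], [0.5, 0, 0]])
    M = C1inv @ M
    eigval, eigvec = np.linalg.eig(M)
    eigval, eigvec = np.real(eigval), np.real(eigvec)
    # admissible eigenvector: 4ac - b^2 > 0
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    idx = np.flatnonzero(cond > 0)
    if len(idx) == 0:
        raise ValueError("ellipse fit failed: no admissible eigenvector")
    a1 = eigvec[:, idx[np.argmin(np.abs(eigval[idx]))]]
    coef = np.concatenate([a1, Tm @ a1])  # in (u, v) frame

    # un-condition back to (x, y)
    A, B, C, D, E, F = coef
    a = A / sc ** 2
    b = B / sc ** 2
    c = C / sc ** 2
    d = (-2 * A * mx - B * my) / sc ** 2 + D / sc
    e = (-B * mx - 2 * C * my) / sc ** 2 + E / sc
    f = (A * mx ** 2 + B * mx * my + C * my ** 2) / sc ** 2 \
        - (D * mx + E * my) / sc + F
    conic = np.array([a, b, c, d, e, f])

    cx, cy, axes, phi = _conic_geometry(conic)
    res_geo = _geometric_residuals(pts, cx, cy, axes, phi)
    centroid = pts.mean(axis=0)
    ss_tot = float(((pts - centroid) ** 2).sum())
    r2_geo = 1.0 - float((res_geo ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0

    # algebraic residuals, gradient-normalized (Sampson distance)
    alg = (a * x * x + b * x * y + c * y * y + d * x + e * y + f)
    gx = 2 * a * x + b * y + d
    gy = b * x + 2 * c * y + e
    sampson = alg / np.sqrt(np.maximum(gx ** 2 + gy ** 2, 1e-300))
    r2_alg = 1.0 - float((sampson ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0

    return EllipseFit(conic=conic, center=(cx, cy),
                      semi_axes=(axes[0], axes[1]), orientation=phi,
                      r_squared=r2_geo, r_squared_algebraic=r2_alg)


def _conic_geometry(conic):
    if conic[0] + conic[2] < 0:  # normalize the conic's overall sign
        conic = -conic
    a, b, c, d, e, f = conic
    A = np.array([[a, b / 2], [b / 2, c]])
    if np.linalg.det(A) <= 0:
        raise ValueError("conic is not an ellipse")
    center = np.linalg.solve(2 * A, [-d, -e])
    cx, cy = center
    # constant term in centered frame
    fc = f + (d * cx + e * cy) / 2.0
    eigval, eigvec = np.linalg.eigh(A)
    if -fc <= 0:
        raise ValueError("degenerate (empty) ellipse")
    axes = np.sqrt(-fc / eigval)  # eigval ascending -> axes descending
    order = np.argsort(axes)[::-1]
    axes = axes[order]
    major_vec = eigvec[:, order[0]]
    phi = float(np.arctan2(major_vec[1], major_vec[0])) % np.pi
    return float(cx), float(cy), (float(axes[0]), float(axes[1])), phi


def _geometric_residuals(pts, cx, cy, axes, phi):
    """Orthogonal distances from points to the ellipse boundary."""
    from scipy.optimize import brentq
    a, b = axes
    ca, sa = np.cos(phi), np.sin(phi)
    R = np.array([[ca, sa], [-sa, ca]])
    local = (pts - [cx, cy]) @ R.T
    out = np.empty(len(pts))
    for k, (p, q) in enumerate(np.abs(local)):
        if p < 1e-12 and q < 1e-12:
            out[k] = min(a, b)
            continue

        def g(th):
            return ((a * a - b * b) * np.cos(th) * np.sin(th)
                    - p * a * np.sin(th) + q * b * np.cos(th))

        if abs(g(0.0)) < 1e-15:
            th = 0.0
        elif abs(g(np.pi / 2)) < 1e-15:
            th = np.pi / 2
        else:
            th = brentq(g, 0.0, np.pi / 2)
        out[k] = np.hypot(a * np.cos(th) - p, b * np.sin(th) - q)
    return out


def noncognate_ratio(apparent_valence: float, cognate_sites: int) -> float:
    """Ratio of non-cognate to cognate stickers on an RNA.

    (apparent_valence - cognate_sites) / cognate_sites, with the cognate
    count the number of consensus binding motifs (UGCAU) on the sequence.
    """
    if cognate_sites <= 0:
        raise ValueError("cognate site count must be positive")
    if apparent_valence < cognate_sites:
        raise ValueError("apparent valence must be >= cognate site count")
    return (apparent_valence - cognate_sites) / cognate_sites


@dataclass
class TieLine:
    """Segment joining coexisting dilute and dense compositions."""

    dilute: tuple
    dense: tuple
    slope: float

    def loglog(self):
        """Endpoints in log10 coordinates (tie lines curve on log axes)."""
        return (tuple(np.log10(self.dilute)), tuple(np.log10(self.dense)))


def tie_line(dilute, dense) -> TieLine:
    """Tie line through per-component (dilute, dense) concentration pairs."""
    dilute = tuple(float(v) for v in dilute)
    dense = tuple(float(v) for v in dense)
    dx = dense[0] - dilute[0]
    dy = dense[1] - dilute[1]
    if dx == 0 and dy == 0:
        raise ValueError("tie line endpoints coincide")
    slope = np.inf if dx == 0 else dy / dx
    return TieLine(dilute=dilute, dense=dense, slope=float(slope))
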