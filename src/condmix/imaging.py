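"""Spot colocalization, pixel-wise correlation, and FRAP trace processing.

Spot statistics operate in 2D pixel coordinates on maximum-intensity
projections.  A reference spot is colocalized when another-channel center
lies strictly closer than twice the spot radius (default r = 1.389 px,
i.e. 150 nm); the pixel-shift control translates the reference centers by
2r along both axes before re-testing, which estimates the chance
coincidence rate.  Nuclear proximity compares spot-to-nucleus-center
distance against r + R with R = sqrt(A / pi) from the segmented nucleus
area; distances >= r + R are "not nuclear proximal" (strict split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_SPOT_RADIUS_PX = 1.389  # 150 nm at 108 nm/px


@dataclass
class SpotField:
    """Detected spot centers of one channel, in pixels."""

    centers: np.ndarray  # (n, 2) float
    spot_radius: float = DEFAULT_SPOT_RADIUS_PX
    pixel_size_nm: float | None = None
    channel: str = ""

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        if self.centers.size == 0:
            self.centers = np.empty((0, 2))
        if self.centers.shape[1] != 2:
            raise ValueError("centers must be (n, 2)")
        if self.spot_radius <= 0:
            raise ValueError("spot radius must be positive")

    def __len__(self):
        return len(self.centers)

    def shifted(self, shift: float) -> "SpotField":
        return SpotField(self.centers + shift, self.spot_radius,
                         self.pixel_size_nm, self.channel)


@dataclass
class NucleusSet:
    """Nucleus centroids and areas; radii derive as R = sqrt(A/pi)."""

    centroids: np.ndarray  # (k, 2)
    areas: np.ndarray      # (k,)

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, float))
        self.areas = np.atleast_1d(np.asarray(self.areas, float))
        if len(self.centroids) != len(self.areas):
            raise ValueError("centroids and areas must align")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def radii(self) -> np.ndarray:
        return np.sqrt(self.areas / np.pi)


def colocalized_fraction(reference: SpotField, other: SpotField) -> float:
    """Fraction of reference spots with an other-channel center < 2r away.

    The threshold uses the reference field's spot radius and a strict
    inequality; both fields must share pixel geometry.
    """
    if len(reference) == 0:
        raise ValueError("reference field is empty")
    if len(other) == 0:
        return 0.0
    thresh = 2.0 * reference.spot_radius
    tree = cKDTree(other.centers)
    d, _ = tree.query(reference.centers, k=1)
    return float(np.mean(d < thresh))


def pixel_shift_control(reference: SpotField, other: SpotField,
                        shift: float | None = None) -> float:
    """Colocalized fraction after shifting reference centers by (+s, +s).

    Default shift is 2r.  Shifted spots that leave the imaged field are
    kept (the distance test remains valid); no wrap-around is applied.
    """
    if shift is None:
        shift = 2.0 * reference.spot_radius
    return colocalized_fraction(reference.shifted(shift), other)


def nuclear_proximal_split(spots: SpotField, nuclei: NucleusSet):
    """Split spots into (nuclear proximal, distal) index arrays.

    Proximal: distance to some nucleus center < r + R (that nucleus's R);
    distal: >= r + R for every nucleus.
    """
    if len(nuclei.centroids) == 0:
        raise ValueError("nucleus set is empty")
    if len(spots) == 0:
        return np.empty(0, int), np.empty(0, int)
    d = np.linalg.norm(spots.centers[:, None, :] - nuclei.centroids[None, :, :],
                       axis=2)
    thresh = spots.spot_radius + nuclei.radii[None, :]
    proximal_mask = np.any(d < thresh, axis=1)
    idx = np.arange(len(spots))
    return idx[proximal_mask], idx[~proximal_mask]


def pearson_colocalization(channel1: np.ndarray, channel2: np.ndarray,
                           mask: np.ndarray | None = None,
                           threshold: float | None = None) -> float:
    """Pixel-wise Pearson correlation between two channels.

    ``mask`` restricts the computation; ``threshold`` optionally keeps only
    pixels where either channel exceeds the given intensity (a crude
    approximation of threshold-regression colocalization).  A constant
    channel leaves the correlation undefined and raises.
    """
    c1 = np.asarray(channel1, float)
    c2 = np.asarray(channel2, float)
    if c1.shape != c2.shape:
        raise ValueError("channels must share shape")
    if mask is None:
        mask = np.ones(c1.shape, bool)
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != c1.shape:
            raise ValueError("mask must share the image shape")
    if threshold is not None:
        mask = mask & ((c1 > threshold) | (c2 > threshold))
    v1, v2 = c1[mask], c2[mask]
    if v1.size < 2:
        raise ValueError("need at least 2 in-mask pixels")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant channel: correlation undefined")
    return float(np.corrcoef(v1, v2)[0, 1])


@dataclass
class FRAPTraces:
    """Raw FRAP intensities for a set of acquisitions.

    Three regions are traced per acquisition: the photobleached spot, an
    unbleached condensate (quality control), and a condensate-free
    background region.  ``pre_bleach_index`` is the index of the first
    post-bleach time point.
    """

    time: np.ndarray        # (T,)
    bleached: np.ndarray    # (A, T)
    unbleached: np.ndarray  # (A, T)
    background: np.ndarray  # (A, T)
    pre_bleach_index: int = 1

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        for name in ("bleached", "unbleached", "background"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), float))
            setattr(self, name, arr)
            if arr.shape[1] != len(self.time):
                raise ValueError(f"{name} length does not match time base")
        if self.bleached.shape[0] < 1:
            raise ValueError("need at least one acquisition")

    @property
    def n_acquisitions(self) -> int:
        return self.bleached.shape[0]


@dataclass
class FRAPResult:
    normalized: np.ndarray      # averaged, background-subtracted, /max
    sem: np.ndarray             # per-time-point SEM across acquisitions
    max_recovery: float         # max over post-bleach points
    max_recovery_sem: float
    passed_qc: np.ndarray       # indices of acquisitions used
    time: np.ndarray


def frap_qc_mask(traces: FRAPTraces, tolerance: float = 0.05) -> np.ndarray:
    """Acquisitions whose unbleached-condensate trace stays within tolerance.

    Deviation is the relative range (max - min) / mean of the unbleached
    ROI over the whole trace; acquisitions deviating by >= tolerance are
    excluded.
    """
    u = traces.unbleached
    dev = (u.max(axis=1) - u.min(axis=1)) / u.mean(axis=1)
    return dev < tolerance


def frap_process(traces: FRAPTraces, qc_tolerance: float = 0.05) -> FRAPResult:
    """Average, background-subtract, and normalize FRAP traces.

    Passing acquisitions are averaged per time point; the mean background
    is subtracted; the trace is divided by the maximum of the averaged
    trace (pre-bleach frames included in the denominator).  max_recovery
    is the maximum normalized value over post-bleach points only.  SEM is
    the across-acquisition standard deviation (of the per-acquisition
    background-subtracted traces on the common normalization scale)
    divided by sqrt(n), per time point and for the post-bleach maxima.
    """
    keep = np.flatnonzero(frap_qc_mask(traces, qc_tolerance))
    if len(keep) == 0:
        raise ValueError("all acquisitions failed the unbleached-ROI QC")
    b = traces.bleached[keep]
    g = traces.background[keep]
    corrected = b - g
    mean_trace = corrected.mean(axis=0)
    denom = mean_trace.max()
    if denom == 0:
        denom = 1.0
    normalized = mean_trace / denom
    per_acq = corrected / denom
    n = len(keep)
    if n > 1:
        sem = per_acq.std(axis=0, ddof=1) / np.sqrt(n)
        maxima = per_acq[:, traces.pre_bleach_index:].max(axis=1)
        max_sem = float(maxima.std(ddof=1) / np.sqrt(n))
    else:
        sem = np.zeros_like(normalized)
        max_sem = 0.0
    max_recovery = float(normalized[traces.pre_bleach_index:].max())
    return FRAPResult(normalized=normalized, sem=sem,
                      max_recovery=max_recovery, max_recovery_sem=max_sem,
                      passed_qc=keep, time=traces.time)
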