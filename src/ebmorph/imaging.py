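"""Per-plane nuclei quantification and intensity profiling.

Implements the confocal quantification chain: Otsu threshold →
distance-transform watershed to split touching nuclei → inclusive 15–350 µm²
area filter; dual-channel (nuclei vs EdU) counting with centroid matching;
diametral and z-axis intensity profiles; and recovery of the concentric zone
radii from Oct4/Gata4 marker sections via angular-averaged radial profiles
and half-maximum crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .containers import SectionImage, ZStack

__all__ = [
    "NucleusObject",
    "NucleiObjects",
    "EdUResult",
    "RadialProfile",
    "segment_nuclei",
    "count_edu_fraction",
    "diametral_profile",
    "zaxis_profile",
    "radial_intensity_profile",
    "measure_pattern_radii",
    "DEFAULT_AREA_RANGE_UM2",
]

# inclusive nucleus area filter, µm²
DEFAULT_AREA_RANGE_UM2: tuple[float, float] = (15.0, 350.0)


@dataclass(frozen=True)
class NucleusObject:
    label: int
    centroid_px: tuple[float, float]  # (row, col)
    area_um2: float


@dataclass
class NucleiObjects:
    """Segmented nuclei of one plane, after area filtering."""

    objects: list[NucleusObject]
    channel: str = "nuclei"
    pixel_size_um: float = 1.0

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def centroids(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 2))
        return np.array([o.centroid_px for o in self.objects])

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([o.area_um2 for o in self.objects])

    def to_frame(self, plane: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            [(plane, o.label, o.centroid_px[1], o.centroid_px[0], o.area_um2,
              self.channel) for o in self.objects],
            columns=["plane", "label", "x", "y", "area_um2", "channel"],
        )


@dataclass
class EdUResult:
    """Per-plane and stack-level EdU-labelled percentages."""

    per_plane_percent: list[float]
    stack_percent: float
    n_planes_used: int
    per_plane_counts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RadialProfile:
    """Intensity sampled along a diametral line (positions in µm)."""

    positions_um: np.ndarray
    intensities: dict[str, np.ndarray]


def segment_nuclei(
    plane: np.ndarray,
    pixel_size_um: float,
    area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE_UM2,
    channel: str = "nuclei",
) -> NucleiObjects:
    """Segment one grayscale plane into nucleus objects.

    Global Otsu threshold, then a watershed on the negated distance
    transform seeded from distance maxima (minimum seed separation: one mean
    nucleus radius from the midpoint of the area filter) to split touching
    nuclei, then an inclusive area filter.  An all-zero/blank plane yields an
    empty result rather than an error.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    plane = np.asarray(plane, dtype=float)
    if plane.max() <= 0 or np.isclose(plane.max(), plane.min()):
        return NucleiObjects([], channel=channel, pixel_size_um=pixel_size_um)
    mask = plane > threshold_otsu(plane)
    if not mask.any():
        return NucleiObjects([], channel=channel, pixel_size_um=pixel_size_um)

    dist = ndi.distance_transform_edt(mask)
    # seeds closer than the radius of the smallest admissible nucleus cannot
    # belong to two distinct in-range nuclei; larger separations start to
    # suppress the seeds of adjacent small nuclei and merge them
    min_radius_px = math.sqrt(area_range_um2[0] / math.pi) / pixel_size_um
    min_sep = max(2, int(round(min_radius_px)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):  # peak order → lowest-label tie-break
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    labels = watershed(-dist, markers, mask=mask)

    lo, hi = area_range_um2
    px_area = pixel_size_um ** 2
    objects = []
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if lo <= area_um2 <= hi:  # inclusive at both bounds
            objects.append(NucleusObject(label=prop.label,
                                         centroid_px=tuple(prop.centroid),
                                         area_um2=float(area_um2)))
    return NucleiObjects(objects, channel=channel, pixel_size_um=pixel_size_um)


def count_edu_fraction(
    stack: ZStack,
    area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE_UM2,
) -> EdUResult:
    """Percent of EdU-labelled nuclei per plane and the unweighted stack mean.

    Both channels are segmented independently; an EdU object counts as a
    labelled nucleus if its centroid lies within one nucleus radius of a
    nucleus centroid (nearest-centroid matching, each nucleus used once).
    Planes with zero segmented nuclei are excluded from the stack mean.
    """
    per_plane, counts = [], []
    for p in range(stack.n_planes):
        nuc = segment_nuclei(stack.channel(0)[p], stack.pixel_size_um,
                             area_range_um2, channel=stack.channel_names[0])
        if len(nuc) == 0:
            continue
        edu = segment_nuclei(stack.channel(1)[p], stack.pixel_size_um,
                             area_range_um2, channel=stack.channel_names[1])
        n_matched = _match_objects(nuc, edu)
        per_plane.append(100.0 * n_matched / len(nuc))
        counts.append((n_matched, len(nuc)))
    if not per_plane:
        raise ValueError("no plane with segmentable nuclei in the stack")
    return EdUResult(
        per_plane_percent=per_plane,
        stack_percent=float(np.mean(per_plane)),
        n_planes_used=len(per_plane),
        per_plane_counts=counts,
    )


def _match_objects(nuclei: NucleiObjects, edu: NucleiObjects) -> int:
    """Count nuclei with an EdU object within one nucleus radius (1:1 greedy)."""
    if len(edu) == 0 or len(nuclei) == 0:
        return 0
    tree = cKDTree(nuclei.centroids)
    radii_px = np.sqrt(nuclei.areas_um2 / math.pi) / nuclei.pixel_size_um
    dists, idx = tree.query(edu.centroids)
    matched: set[int] = set()
    for d, i in sorted(zip(dists, idx)):
        if i not in matched and d <= radii_px[i]:
            matched.add(int(i))
    return len(matched)


def _foreground_mask(section: SectionImage) -> np.ndarray:
    """Filled EB mask: union of channels above Otsu, holes (cavity) filled."""
    combined = section.data.max(axis=0)
    mask = combined > threshold_otsu(combined)
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n > 1:  # keep the largest component (stray noise specks)
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def diametral_profile(
    section: SectionImage,
    center: tuple[float, float] | None = None,
    angle: float = 0.0,
) -> RadialProfile:
    """Bilinear intensity profile along a diametral line through the EB.

    The line passes through ``center`` (defaults to the mask centroid) at
    ``angle`` radians and is clipped to the EB mask; samples are 1 px apart
    and positions are reported in µm from the line start.
    """
    mask = _foreground_mask(section)
    if center is None:
        cy, cx = ndi.center_of_mass(mask)
    else:
        cy, cx = center
    if not mask[int(round(cy)), int(round(cx))]:
        raise ValueError("line center lies outside the EB mask")
    dy, dx = math.sin(angle), math.cos(angle)
    diag = math.hypot(*mask.shape)
    t = np.arange(-diag, diag + 1.0, 1.0)
    ys, xs = cy + t * dy, cx + t * dx
    inb = (ys >= 0) & (ys <= mask.shape[0] - 1) & (xs >= 0) & (xs <= mask.shape[1] - 1)
    ys, xs, t = ys[inb], xs[inb], t[inb]
    inside = ndi.map_coordinates(mask.astype(float), [ys, xs], order=0) > 0.5
    if not inside.any():
        raise ValueError("line does not intersect the EB mask")
    sel = np.where(inside)[0]
    first, last = sel[0], sel[-1]
    ys, xs, t = ys[first:last + 1], xs[first:last + 1], t[first:last + 1]
    positions = (t - t[0]) * section.pixel_size_um
    intensities = {
        name: ndi.map_coordinates(section.channel(i).astype(float), [ys, xs], order=1)
        for i, name in enumerate(section.channel_names)
    }
    return RadialProfile(positions_um=positions, intensities=intensities)


def zaxis_profile(
    stack: ZStack,
    roi_center_px: tuple[float, float] | None = None,
    roi_size_um: tuple[float, float] = (100.0, 100.0),
) -> pd.DataFrame:
    """Mean intensity inside a rectangular ROI, per plane and channel.

    The ROI (default 100×100 µm) is centred on ``roi_center_px`` (image
    centre by default) and must lie fully inside the image bounds.
    """
    h, w = stack.shape
    if roi_center_px is None:
        roi_center_px = ((h - 1) / 2.0, (w - 1) / 2.0)
    half_h = roi_size_um[0] / stack.pixel_size_um / 2.0
    half_w = roi_size_um[1] / stack.pixel_size_um / 2.0
    r0, r1 = int(round(roi_center_px[0] - half_h)), int(round(roi_center_px[0] + half_h))
    c0, c1 = int(round(roi_center_px[1] - half_w)), int(round(roi_center_px[1] + half_w))
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError("ROI extends outside the image bounds")
    rows = []
    for p in range(stack.n_planes):
        rec = {"plane": p}
        for i, name in enumerate(stack.channel_names):
            rec[name] = float(stack.data[i, p, r0:r1, c0:c1].mean())
        rows.append(rec)
    return pd.DataFrame(rows)


def radial_intensity_profile(
    section: SectionImage, center: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Angular-averaged intensity vs integer radius (px) for each channel."""
    mask = _foreground_mask(section)
    if center is None:
        center = ndi.center_of_mass(mask)
    cy, cx = center
    yy, xx = np.indices(mask.shape)
    r = np.hypot(yy - cy, xx - cx)
    r_int = r.astype(int)
    n_bins = int(r_int.max()) + 1
    counts = np.bincount(r_int.ravel(), minlength=n_bins)
    out = {"radius_px": np.arange(n_bins)}
    for i, name in enumerate(section.channel_names):
        sums = np.bincount(r_int.ravel(), weights=section.channel(i).ravel().astype(float),
                           minlength=n_bins)
        out[name] = sums / np.maximum(counts, 1)
    out["mask_coverage"] = (
        np.bincount(r_int.ravel(), weights=mask.ravel().astype(float), minlength=n_bins)
        / np.maximum(counts, 1)
    )
    return pd.DataFrame(out)


def _half_max_crossing(radii: np.ndarray, values: np.ndarray, half: float,
                       rising: bool) -> float:
    """First radius where ``values`` crosses ``half`` (linear interpolation)."""
    above = values >= half
    for i in range(1, len(values)):
        if rising and above[i] and not above[i - 1]:
            lo, hi = values[i - 1], values[i]
            frac = (half - lo) / (hi - lo) if hi != lo else 0.0
            return float(radii[i - 1] + frac * (radii[i] - radii[i - 1]))
        if not rising and not above[i] and above[i - 1]:
            lo, hi = values[i - 1], values[i]
            frac = (lo - half) / (lo - hi) if lo != hi else 0.0
            return float(radii[i - 1] + frac * (radii[i] - radii[i - 1]))
    return float("nan")


def measure_pattern_radii(section: SectionImage) -> tuple[float, float, float]:
    """Recover (cavity_d, epil_outer_d, total_d) in µm from a marker section.

    Boundaries come from the angular-averaged radial profile: the cavity
    edge is the inner half-maximum rise of the Oct4 channel (0 if Oct4 is
    already bright at the centre), the Epi-l/ExEn boundary the inner
    half-maximum rise of Gata4 (total diameter if Gata4 carries no ring),
    and the total diameter the half-coverage falloff of the EB mask.
    """
    prof = radial_intensity_profile(section)
    radii = prof["radius_px"].to_numpy().astype(float)
    oct4 = prof[section.channel_names[1]].to_numpy()
    gata4 = prof[section.channel_names[0]].to_numpy()
    coverage = prof["mask_coverage"].to_numpy()

    r_total = _half_max_crossing(radii, coverage, 0.5, rising=False)
    if math.isnan(r_total):
        r_total = radii[coverage > 0.5].max() if (coverage > 0.5).any() else radii[-1]
    n_in = max(3, int(r_total))

    oct4_in = oct4[:n_in]
    peak = oct4_in.max()
    base = oct4_in.min()
    if peak <= 0 or oct4_in[0] >= 0.5 * (peak + base):
        r_cav = 0.0  # Oct4 bright at the centre: no detectable cavity
    else:
        half = 0.5 * (peak + base)
        r_cav = _half_max_crossing(radii[:n_in], oct4_in, half, rising=True)
        if math.isnan(r_cav):
            r_cav = 0.0

    gata4_in = gata4[:n_in]
    g_peak, g_base = gata4_in.max(), gata4_in.min()
    # no ExEn ring if Gata4 never clearly exceeds its interior baseline
    if g_peak < 2 * max(g_base, 1e-6) or g_peak - g_base < 0.05:
        r_epi = r_total
    else:
        half = 0.5 * (g_peak + g_base)
        # search outward starting past the cavity
        start = int(math.ceil(r_cav))
        r_epi = _half_max_crossing(radii[start:n_in], gata4_in[start:], half, rising=True)
        if math.isnan(r_epi):
            r_epi = r_total
    px = section.pixel_size_um
    return 2 * r_cav * px, 2 * r_epi * px, 2 * r_total * px
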