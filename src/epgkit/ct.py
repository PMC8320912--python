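"""CT segmentation and electrode-placement asymmetry of an artificial palate.

A cone-beam CT of an EPG palate fixed on its plaster cast shows three
intensity classes: air (dark), the stone cast (intermediate) and the
metallic elements — electrodes and retaining wires (bright).  The pipeline:

1. Dual ("Schmitt-trigger") thresholding: a low threshold segments the
   background and a high one the metal candidates, leaving the middle band
   as the cast candidate.  Metal artefacts make single-threshold
   segmentation fail, hence the two-threshold scheme.
2. Morphological refinement of the cast (closing, opening, hole filling);
   bright voxels inside the refined cast are artefacts and are discarded
   from the metal candidates.
3. Wires are separated from electrodes by connected-component size.
4. Electrodes are uniquely labelled and their centroids computed.
5. A sagittal symmetry plane (orthogonal to the left-right axis) splits
   the electrodes into sides; each centroid is reflected through the plane
   and matched to its nearest opposite-side electrode.  The distance
   between an electrode and the reflection of its counterpart (the
   *mirror distance*) quantifies placement asymmetry; the distance to the
   nearest same-side neighbour provides the comparison scale.

Coordinates are 0-based ``[z, y, x]`` voxel indices: x is the left-right
axis, the anterior direction is decreasing y (axial slices with the
incisors at the top).  Distances are reported in voxels (primary) and mm.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_multiotsu

__all__ = [
    "CTVolume",
    "SegmentationMasks",
    "Electrode",
    "ElectrodeSet",
    "SymmetryPlane",
    "MirrorAnalysis",
    "load_ct",
    "auto_thresholds",
    "double_threshold",
    "refine_cast",
    "split_wires_electrodes",
    "label_electrodes",
    "estimate_plane",
    "assign_sides",
    "mirror_project",
    "distance_histograms",
    "segment_palate",
    "electrode_table",
]


@dataclass
class CTVolume:
    """A 3-D intensity volume with voxel spacing in mm.

    ``intensities`` is indexed ``[z, y, x]`` (axial slices stacked along z);
    ``spacing`` gives mm per voxel along each of those axes.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("CTVolume requires a 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("CT intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class SegmentationMasks:
    """Binary masks for the four structures in the scan."""

    background: np.ndarray
    cast: np.ndarray
    wires: np.ndarray
    electrodes: np.ndarray


@dataclass
class Electrode:
    id: int
    centroid_vox: tuple[float, float, float]  # (z, y, x)
    centroid_mm: tuple[float, float, float]
    volume: int
    side: str | None = None  # "left" / "right" once assigned


@dataclass
class ElectrodeSet:
    electrodes: list[Electrode]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __len__(self) -> int:
        return len(self.electrodes)

    def centroids(self) -> np.ndarray:
        return np.array([e.centroid_vox for e in self.electrodes], dtype=float)

    def by_side(self, side: str) -> list[Electrode]:
        return [e for e in self.electrodes if e.side == side]


@dataclass(frozen=True)
class SymmetryPlane:
    """A plane orthogonal to one voxel axis (default x, the left-right axis)."""

    offset: float
    axis: int = 2

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Reflect (z, y, x) points through the plane (an involution)."""
        pts = np.array(points, dtype=float, copy=True)
        pts[..., self.axis] = 2.0 * self.offset - pts[..., self.axis]
        return pts


@dataclass
class MirrorPairing:
    electrode_id: int
    partner_id: int
    reflection_vox: tuple[float, float, float]
    distance_vox: float
    distance_mm: float


@dataclass
class MirrorAnalysis:
    """Mirror pairings, neighbour distances and their summary statistics."""

    pairings: list[MirrorPairing]
    neighbour_distances: list[tuple[int, int, float]]  # (id, nearest same-side id, vox)
    summaries: dict[str, dict[str, float]]
    unmatched: list[int] = field(default_factory=list)

    @property
    def mirror_distances_vox(self) -> np.ndarray:
        return np.array([p.distance_vox for p in self.pairings])

    @property
    def neighbour_distances_vox(self) -> np.ndarray:
        return np.array([d for _, _, d in self.neighbour_distances])

    def overlap_statistic(self) -> float:
        """Fraction of mirror distances exceeding the minimum neighbour distance.

        0 means the two distance distributions do not overlap at all —
        placement asymmetry is negligible on the scale of the electrode
        grid.
        """
        m = self.mirror_distances_vox
        nb = self.neighbour_distances_vox
        if m.size == 0 or nb.size == 0:
            raise ValueError("overlap statistic undefined without both distance sets")
        return float(np.mean(m > nb.min()))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_ct(path: str | Path) -> CTVolume:
    """Load a CT volume from a DICOM series directory or a ``.npy`` + sidecar.

    A directory is read as a DICOM series (slices sorted by their position
    along the slice axis, falling back to InstanceNumber).  A ``.npy`` file
    is loaded directly, with spacing taken from a JSON sidecar
    ``<stem>.json`` holding ``{"spacing": [z, y, x]}`` (default 1 mm).
    """
    path = Path(path)
    if path.is_dir():
        import pydicom

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
        slices = []
        for f in files:
            if not f.is_file():
                continue
            try:
                slices.append(pydicom.dcmread(str(f)))
            except Exception:
                continue
        if not slices:
            raise FileNotFoundError(f"no readable DICOM slices in {path}")

        def sort_key(ds):
            ipp = getattr(ds, "ImagePositionPatient", None)
            if ipp is not None:
                return float(ipp[2])
            return float(getattr(ds, "InstanceNumber", 0))

        slices.sort(key=sort_key)
        vol = np.stack([s.pixel_array.astype(np.float64) for s in slices])
        slope = float(getattr(slices[0], "RescaleSlope", 1.0))
        intercept = float(getattr(slices[0], "RescaleIntercept", 0.0))
        vol = vol * slope + intercept
        px = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
        if len(slices) > 1:
            try:
                dz = abs(sort_key(slices[1]) - sort_key(slices[0])) or 1.0
            except Exception:
                dz = float(getattr(slices[0], "SliceThickness", 1.0))
        else:
            dz = float(getattr(slices[0], "SliceThickness", 1.0))
        return CTVolume(vol, (dz, float(px[0]), float(px[1])))
    if path.suffix == ".npy":
        vol = np.load(path)
        sidecar = path.with_suffix(".json")
        spacing = (1.0, 1.0, 1.0)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta.get("spacing", spacing))
        return CTVolume(vol, spacing)
    raise ValueError(f"cannot load CT from {path}: expected a directory or .npy file")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def auto_thresholds(vol: CTVolume) -> tuple[float, float]:
    """Data-driven (t_low, t_high) via three-class multi-level Otsu."""
    t_low, t_high = threshold_multiotsu(vol.intensities, classes=3)
    return float(t_low), float(t_high)


def double_threshold(
    vol: CTVolume, t_low: float, t_high: float
) -> tuple[np.ndarray, np.ndarray]:
    """Schmitt-trigger-style dual thresholding.

    Returns ``(background, bright)``: voxels below ``t_low`` and above
    ``t_high`` respectively.  The middle band (neither mask) is the cast
    candidate.  Thresholds outside the intensity range trigger a warning
    (the corresponding mask may be empty).
    """
    if not t_low < t_high:
        raise ValueError(f"t_low ({t_low}) must be below t_high ({t_high})")
    lo, hi = vol.intensities.min(), vol.intensities.max()
    if t_low < lo or t_high > hi:
        warnings.warn(
            f"thresholds ({t_low}, {t_high}) outside intensity range [{lo}, {hi}]",
            stacklevel=2,
        )
    background = vol.intensities < t_low
    bright = vol.intensities > t_high
    return background, bright


def refine_cast(
    vol: CTVolume,
    background: np.ndarray,
    bright: np.ndarray,
    radius: int = 2,
) -> np.ndarray:
    """Refine the cast mask with closing, opening and hole filling.

    The cast candidate is the middle intensity band (neither background
    nor bright).  Closing bridges small gaps, opening removes speckle, and
    hole filling absorbs internal cavities — including bright artefact
    blobs embedded in the cast, whose voxels are thereby excluded from the
    metal candidates downstream.

    Raises if the refined cast is empty.
    """
    if background.shape != bright.shape or background.shape != vol.shape:
        raise ValueError("masks must match the volume shape")
    middle = ~background & ~bright
    ball = morphology.ball(radius)
    cast = morphology.closing(middle, ball)
    cast = morphology.opening(cast, ball)
    cast = ndimage.binary_fill_holes(cast)
    if not cast.any():
        raise ValueError("cast mask empty after morphological refinement")
    return cast


def split_wires_electrodes(
    metal: np.ndarray, size_threshold: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """Separate wires from electrodes by connected-component size.

    Components (26-connected) with more than ``size_threshold`` voxels are
    wires — the retaining wires are long thin structures far larger than
    any electrode; a component exactly at the threshold counts as an
    electrode.  Warns when the metal mask has no components at all.
    """
    labels = measure.label(metal, connectivity=3)
    if labels.max() == 0:
        warnings.warn("no metal components found", stacklevel=2)
        empty = np.zeros_like(metal, dtype=bool)
        return empty, empty.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    wire_ids = np.flatnonzero(sizes > size_threshold)
    wires = np.isin(labels, wire_ids)
    electrodes = (labels > 0) & ~wires
    return wires, electrodes


def label_electrodes(
    electrodes_mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> ElectrodeSet:
    """Uniquely label electrode components and compute their centroids.

    Components are 26-connected; touching electrodes therefore merge into
    one component (documented behaviour).  Ids are assigned in
    anterior-to-posterior (ascending y), then left-to-right (ascending x)
    centroid order, starting at 1.
    """
    if not electrodes_mask.any():
        raise ValueError("electrode mask is empty")
    labels = measure.label(electrodes_mask, connectivity=3)
    props = measure.regionprops(labels)
    items = []
    for p in props:
        cz, cy, cx = p.centroid
        items.append((cy, cx, cz, int(p.area)))
    items.sort(key=lambda t: (t[0], t[1]))
    electrodes = [
        Electrode(
            id=i + 1,
            centroid_vox=(cz, cy, cx),
            centroid_mm=(cz * spacing[0], cy * spacing[1], cx * spacing[2]),
            volume=vol,
        )
        for i, (cy, cx, cz, vol) in enumerate(items)
    ]
    return ElectrodeSet(electrodes=electrodes, spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# Symmetry plane and mirror analysis
# ---------------------------------------------------------------------------

def assign_sides(es: ElectrodeSet, plane: SymmetryPlane) -> ElectrodeSet:
    """Assign each electrode to the left or right of the symmetry plane.

    Left is the low-coordinate side of the plane axis.  A centroid lying
    exactly on the plane is an error: the user must adjust the plane
    offset.  All electrodes on one side only triggers a warning.
    """
    on_plane = [
        e.id for e in es.electrodes if e.centroid_vox[plane.axis] == plane.offset
    ]
    if on_plane:
        raise ValueError(
            f"electrode(s) {on_plane} lie exactly on the symmetry plane "
            f"(offset {plane.offset}); adjust the plane offset"
        )
    for e in es.electrodes:
        e.side = "left" if e.centroid_vox[plane.axis] < plane.offset else "right"
    sides = {e.side for e in es.electrodes}
    if len(sides) == 1:
        warnings.warn("all electrodes fall on one side of the plane", stacklevel=2)
    return es


def _greedy_match(
    left_pts: np.ndarray, right_pts: np.ndarray, plane: SymmetryPlane
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one pairing by ascending reflected distance.

    Returns (left_idx, right_idx, distance_vox) triples.  The distance is
    symmetric: |reflect(p_L) - p_R| == |p_L - reflect(p_R)|.
    """
    if len(left_pts) == 0 or len(right_pts) == 0:
        return []
    refl = plane.reflect(left_pts)
    d = np.linalg.norm(refl[:, None, :] - right_pts[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for i, j in order:
        if i in used_l or j in used_r:
            continue
        used_l.add(int(i))
        used_r.add(int(j))
        pairs.append((int(i), int(j), float(d[i, j])))
        if len(used_l) == min(len(left_pts), len(right_pts)):
            break
    return pairs


def estimate_plane(
    es: ElectrodeSet, axis: int = 2, step: float = 0.25
) -> SymmetryPlane:
    """Estimate the sagittal symmetry plane from the electrode centroids.

    Grid search over candidate offsets along ``axis``, choosing the offset
    that minimises the mean mirror-pair distance under greedy one-to-one
    matching.  A manually chosen offset can always be used instead by
    constructing :class:`SymmetryPlane` directly (the plane of a properly
    oriented acquisition sits in the gap between the two frontal teeth).

    Degenerate sets (all centroids at one coordinate) fall back to the
    median coordinate.
    """
    pts = es.centroids()
    if len(pts) < 2:
        raise ValueError("plane estimation needs at least 2 electrodes")
    coords = pts[:, axis]
    lo, hi = coords.min(), coords.max()
    if hi - lo < 1e-9:
        return SymmetryPlane(offset=float(np.median(coords)), axis=axis)
    if len(pts) == 2:
        return SymmetryPlane(offset=float(coords.mean()), axis=axis)
    best_offset, best_cost = None, np.inf
    # grid aligned to multiples of `step` so symmetric configurations are hit exactly
    candidates = np.arange(math.ceil(lo / step), math.floor(hi / step) + 1) * step
    for offset in candidates:
        left = pts[coords < offset]
        right = pts[coords > offset]
        if len(left) == 0 or len(right) == 0:
            continue
        plane = SymmetryPlane(offset=float(offset), axis=axis)
        pairs = _greedy_match(left, right, plane)
        n_unmatched = abs(len(left) - len(right))
        if not pairs:
            continue
        # Penalise unbalanced splits so the plane centres the grid.
        cost = float(np.mean([p[2] for p in pairs])) + 10.0 * step * n_unmatched
        if cost < best_cost:
            best_cost, best_offset = cost, float(offset)
    if best_offset is None:
        best_offset = float(np.median(coords))
    return SymmetryPlane(offset=best_offset, axis=axis)


def mirror_project(es: ElectrodeSet, plane: SymmetryPlane) -> MirrorAnalysis:
    """Reflect electrodes through the symmetry plane and measure asymmetry.

    Each centroid is reflected through the plane; its partner is the
    nearest opposite-side electrode under greedy one-to-one matching by
    ascending distance.  For a perfectly symmetrical palate every
    reflection lands exactly on the partner electrode and all mirror
    distances are zero.  Also records, for every electrode, the distance
    to its nearest same-side neighbour, which sets the spatial scale of
    the electrode grid.

    Unbalanced sides leave the surplus electrodes unmatched; they are
    listed in ``unmatched``, excluded from the summaries, and warned about.
    """
    left = es.by_side("left")
    right = es.by_side("right")
    if not left or not right:
        raise ValueError("mirror projection requires electrodes on both sides")
    lp = np.array([e.centroid_vox for e in left])
    rp = np.array([e.centroid_vox for e in right])
    spacing = np.asarray(es.spacing)

    pairs = _greedy_match(lp, rp, plane)
    pairings: list[MirrorPairing] = []
    for i, j, d_vox in pairs:
        refl = plane.reflect(lp[i])
        d_mm = float(np.linalg.norm((refl - rp[j]) * spacing))
        pairings.append(
            MirrorPairing(
                electrode_id=left[i].id,
                partner_id=right[j].id,
                reflection_vox=tuple(refl),
                distance_vox=d_vox,
                distance_mm=d_mm,
            )
        )
    matched_l = {p.electrode_id for p in pairings}
    matched_r = {p.partner_id for p in pairings}
    unmatched = [e.id for e in left if e.id not in matched_l] + [
        e.id for e in right if e.id not in matched_r
    ]
    if unmatched:
        warnings.warn(
            f"unbalanced sides: electrodes {unmatched} have no mirror partner",
            stacklevel=2,
        )

    neighbour: list[tuple[int, int, float]] = []
    for group in (left, right):
        if len(group) < 2:
            continue
        pts = np.array([e.centroid_vox for e in group])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        for k, e in enumerate(group):
            neighbour.append((e.id, group[nearest[k]].id, float(d[k, nearest[k]])))

    def stats(x: np.ndarray) -> dict[str, float]:
        if x.size == 0:
            return {"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan, "n": 0}
        return {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "min": float(x.min()),
            "max": float(x.max()),
            "n": int(x.size),
        }

    mirror_vox = np.array([p.distance_vox for p in pairings])
    mirror_mm = np.array([p.distance_mm for p in pairings])
    nb_vox = np.array([d for _, _, d in neighbour])
    summaries = {
        "mirror_vox": stats(mirror_vox),
        "mirror_mm": stats(mirror_mm),
        "neighbour_vox": stats(nb_vox),
    }
    return MirrorAnalysis(
        pairings=pairings,
        neighbour_distances=neighbour,
        summaries=summaries,
        unmatched=unmatched,
    )


def distance_histograms(ma: MirrorAnalysis, ax=None) -> tuple:
    """Histogram mirror vs neighbour distances on a shared axis.

    Returns ``(ax, table)`` where the table holds the summary statistics
    plus the overlap statistic (fraction of mirror distances exceeding the
    minimum neighbour distance).  Raises when either distance set is empty.
    """
    import matplotlib.pyplot as plt

    m = ma.mirror_distances_vox
    nb = ma.neighbour_distances_vox
    if m.size == 0 or nb.size == 0:
        raise ValueError("cannot histogram empty distance sets")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    bins = np.histogram_bin_edges(np.concatenate([m, nb]), bins=20)
    ax.hist(m, bins=bins, histtype="step", color="tab:blue", lw=1.8,
            label="electrode vs mirror projection")
    ax.hist(nb, bins=bins, histtype="step", color="tab:red", ls="--", lw=1.8,
            label="neighbouring electrodes")
    ax.set_xlabel("distance (voxels)")
    ax.set_ylabel("count")
    ax.legend()
    overlap = ma.overlap_statistic()
    rows = []
    for name, s in ma.summaries.items():
        rows.append({"set": name, **s})
    table = pd.DataFrame(rows)
    table.attrs["overlap_statistic"] = overlap
    return ax, table


def electrode_table(es: ElectrodeSet, ma: MirrorAnalysis | None = None) -> pd.DataFrame:
    """Tabulate electrodes (id, centroid, volume, side, mirror info)."""
    partner = {}
    dist_vox = {}
    dist_mm = {}
    nb = {}
    if ma is not None:
        for p in ma.pairings:
            partner[p.electrode_id] = p.partner_id
            partner[p.partner_id] = p.electrode_id
            dist_vox[p.electrode_id] = dist_vox[p.partner_id] = p.distance_vox
            dist_mm[p.electrode_id] = dist_mm[p.partner_id] = p.distance_mm
        for i, _, d in ma.neighbour_distances:
            nb[i] = d
    rows = []
    for e in es.electrodes:
        z, y, x = e.centroid_vox
        rows.append(
            {
                "id": e.id,
                "x": x,
                "y": y,
                "z": z,
                "volume": e.volume,
                "side": e.side,
                "mirror_partner": partner.get(e.id),
                "mirror_distance_vox": dist_vox.get(e.id),
                "mirror_distance_mm": dist_mm.get(e.id),
                "neighbour_distance_vox": nb.get(e.id),
            }
        )
    return pd.DataFrame(rows)


def segment_palate(
    vol: CTVolume,
    t_low: float | None = None,
    t_high: float | None = None,
    radius: int = 2,
    size_threshold: int = 300,
    plane_offset: float | None = None,
) -> tuple[SegmentationMasks, ElectrodeSet, SymmetryPlane, MirrorAnalysis]:
    """Run the full segmentation and asymmetry pipeline on a CT volume.

    Thresholds default to three-class Otsu; the symmetry plane defaults to
    the grid-search estimate and can be fixed manually via
    ``plane_offset``.
    """
    if t_low is None or t_high is None:
        a_low, a_high = auto_thresholds(vol)
        t_low = a_low if t_low is None else t_low
        t_high = a_high if t_high is None else t_high
    background, bright = double_threshold(vol, t_low, t_high)
    cast = refine_cast(vol, background, bright, radius=radius)
    metal = bright & ~cast
    wires, electrodes_mask = split_wires_electrodes(metal, size_threshold=size_threshold)
    es = label_electrodes(electrodes_mask, spacing=vol.spacing)
    plane = (
        SymmetryPlane(offset=float(plane_offset))
        if plane_offset is not None
        else estimate_plane(es)
    )
    assign_sides(es, plane)
    ma = mirror_project(es, plane)
    masks = SegmentationMasks(
        background=background, cast=cast, wires=wires, electrodes=electrodes_mask
    )
    return masks, es, plane, ma
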