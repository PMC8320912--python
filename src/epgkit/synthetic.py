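"""Synthetic fixtures: simulated EPG sentences and CT phantoms.

Real electropalatography corpora and palate CT scans are bulky and not
redistributable, so every test input is generated here with known ground
truth.  Two generators are provided:

* :func:`simulate_sentence` builds a phoneme timeline, a palatogram
  sequence drawn from per-phoneme contact-probability templates with a
  controllable left-right bias, and a placeholder audio signal (one
  sinusoid per phoneme plus noise at 16 kHz) — enough structure for
  spectrogram and alignment tests, not a model of real acoustics.
* :func:`build_phantom` renders a CT phantom of a palate cast with
  spherical electrodes at mirror-symmetric base positions (plus optional
  planted per-electrode offsets) and long wire tubes, with three
  well-separated intensity classes plus Gaussian noise.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ct import CTVolume, Electrode, ElectrodeSet
from .formats import PhonemeInterval, PhonemeTimeline
from .audio_spectral import AudioSignal
from .palatogram import PalateLayout, PalatogramSequence

__all__ = [
    "EPGSimSpec",
    "PhantomSpec",
    "default_templates",
    "simulate_sentence",
    "build_phantom",
    "planted_offsets",
]


def default_templates(layout: PalateLayout) -> dict[str, np.ndarray]:
    """Per-phoneme activation-probability templates on a layout.

    Coarse caricatures of real contact patterns: alveolars ([t, d, s])
    contact the anterior rows, the velar [ng] the posterior rows, laterals
    and vowels mainly the lateral margins, and silence nothing.  Values
    are per-electrode Bernoulli probabilities.
    """
    R, W = layout.n_rows, layout.max_width
    rows = np.arange(R)[:, None] * np.ones((1, W))
    off_l = np.zeros((R, W), dtype=bool)
    # lateral margins: outermost valid column on each side of each row
    margins = np.zeros((R, W))
    for r in range(R):
        cols = np.flatnonzero(layout.valid[r])
        margins[r, cols[0]] = margins[r, cols[-1]] = 1.0
        if len(cols) > 2:
            margins[r, cols[1]] = margins[r, cols[-2]] = 0.6

    def clipped(a):
        out = np.where(layout.valid, a, 0.0)
        return np.clip(out, 0.0, 0.95)

    anterior = clipped(np.exp(-rows / 1.5) * 0.9 + margins * 0.4)
    posterior = clipped(np.exp(-(R - 1 - rows) / 1.5) * 0.9 + margins * 0.4)
    lateral = clipped(margins * 0.8)
    templates = {
        "t": anterior,
        "d": anterior,
        "s": clipped(np.exp(-rows / 2.0) * 0.85 + margins * 0.5),
        "ng": posterior,
        "k": posterior,
        "l": clipped(np.exp(-rows / 1.2) * 0.7),
        "ih": lateral,
        "iy": clipped(margins * 0.9),
        "ah": clipped(margins * 0.3),
        "sil": np.zeros((R, W)),
        "breath": np.zeros((R, W)),
    }
    return templates


@dataclass
class EPGSimSpec:
    """Specification for a simulated EPG recording.

    Parameters
    ----------
    layout : PalateLayout
        Electrode grid (default Reading-style 62-electrode palate).
    frame_rate : float
        Palatogram rate in Hz; 200 Hz matches standard EPG3 hardware.
    templates : dict, optional
        label -> per-electrode activation probability; defaults to
        :func:`default_templates`.
    left_bias : float in [0, 1]
        For each mirror electrode pair, the pair's total activation
        probability mass is reallocated so a fraction ``left_bias`` goes
        to the left electrode.  0.5 leaves symmetric templates symmetric;
        the expected left activation fraction of the generated frames
        equals ``left_bias``.
    seed : int
        Seed for the generator; outputs are deterministic given the spec.
    """

    layout: PalateLayout = field(default_factory=PalateLayout.reading62)
    frame_rate: float = 200.0
    templates: dict[str, np.ndarray] | None = None
    left_bias: float = 0.5
    sample_rate: float = 16000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.left_bias <= 1.0:
            raise ValueError("left_bias must be in [0, 1]")
        if self.templates is None:
            self.templates = default_templates(self.layout)
        for label, t in self.templates.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (self.layout.n_rows, self.layout.max_width):
                raise ValueError(f"template {label!r} shape does not match layout")
            if t.min() < 0 or t.max() > 1:
                raise ValueError(f"template {label!r} probabilities outside [0, 1]")
            self.templates[label] = t


def _biased_template(spec: EPGSimSpec, template: np.ndarray) -> np.ndarray:
    """Shift each mirror pair's probability mass left/right by left_bias.

    The pair's total mass m = p_L + p_R is reallocated as (m*b, m*(1-b)).
    When that would push one probability above 1 the mass is scaled down so
    the larger share is exactly 1 — the left/right *ratio* b : (1-b) is
    always preserved, which is what makes the expected left activation
    fraction of the generated frames equal the bias.
    """
    lay = spec.layout
    b = spec.left_bias
    out = template.copy()
    for r, c in lay.positions:
        if lay.side[r, c] >= 0:  # handle each pair once, from its left member
            continue
        cm = lay.mirror_col[r, c]
        mass = template[r, c] + template[r, cm]
        top = max(b, 1.0 - b)
        if mass * top > 1.0:
            mass = 1.0 / top
        out[r, c] = mass * b
        out[r, cm] = mass * (1.0 - b)
    return out


def simulate_sentence(
    spec: EPGSimSpec, phonemes: Sequence[tuple[str, float]]
) -> tuple[PhonemeTimeline, PalatogramSequence, AudioSignal]:
    """Simulate one annotated sentence.

    Parameters
    ----------
    phonemes : sequence of (label, duration_seconds)
        The phoneme string with per-phoneme durations (> 0).

    Returns
    -------
    (PhonemeTimeline, PalatogramSequence, AudioSignal)
        Timeline matching the request; frames drawn per-electrode
        Bernoulli from the active phoneme's bias-adjusted template; audio
        as a per-phoneme sinusoid (frequency derived from the label) with
        additive noise.

    Raises
    ------
    KeyError
        For a phoneme label with no template.
    """
    rng = np.random.default_rng(spec.seed)
    lay = spec.layout
    intervals: list[PhonemeInterval] = []
    t = 0.0
    all_frames = []
    audio_chunks = []
    for label, dur in phonemes:
        if dur <= 0:
            raise ValueError(f"phoneme {label!r} has non-positive duration {dur}")
        if label not in spec.templates:
            raise KeyError(f"no contact template for phoneme {label!r}")
        intervals.append(PhonemeInterval(label, t, t + dur))
        n = max(int(round(dur * spec.frame_rate)), 1)
        probs = _biased_template(spec, spec.templates[label])
        frames = (rng.random((n, lay.n_rows, lay.max_width)) < probs).astype(np.uint8)
        frames[:, ~lay.valid] = 0
        all_frames.append(frames)

        ns = int(round(dur * spec.sample_rate))
        tt = (np.arange(ns) + round(t * spec.sample_rate)) / spec.sample_rate
        if label in ("sil", "breath"):
            chunk = 0.002 * rng.standard_normal(ns)
        else:
            freq = 200.0 + (sum(ord(ch) for ch in label) * 37) % 3000
            chunk = 0.5 * np.sin(2 * np.pi * freq * tt) + 0.02 * rng.standard_normal(ns)
        audio_chunks.append(chunk)
        t += dur

    timeline = PhonemeTimeline(phonemes=intervals)
    seq = PalatogramSequence(
        frames=np.concatenate(all_frames, axis=0)
        if all_frames
        else np.zeros((0, lay.n_rows, lay.max_width), np.uint8),
        frame_rate=spec.frame_rate,
        layout=lay,
    )
    audio = AudioSignal(
        samples=np.clip(np.concatenate(audio_chunks), -1, 1)
        if audio_chunks
        else np.zeros(0),
        sample_rate=spec.sample_rate,
    )
    return timeline, seq, audio


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Specification for a palate CT phantom.

    The phantom renders a solid cast slab (with a dome profile), 62
    spherical electrodes arranged in the Reading-style 8-row horseshoe at
    positions mirror-symmetric about the mid-sagittal plane, and two long
    wire tubes, at three separable intensity levels plus Gaussian noise.

    ``offsets`` (shape ``(n_electrodes, 3)``, voxels, (z, y, x) order) is
    added to the base electrode positions to plant known placement
    asymmetry; with offsets applied to one side only and the true plane,
    each mirror distance equals the magnitude of that electrode's offset.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: float = 0.3  # mm, isotropic
    electrodes_per_row: tuple[int, ...] = (6, 8, 8, 8, 8, 8, 8, 8)
    electrode_radius: float = 2.5
    offsets: np.ndarray | None = None
    background_intensity: float = 0.0
    cast_intensity: float = 500.0
    metal_intensity: float = 2000.0
    noise_sd: float = 20.0
    seed: int = 0

    @classmethod
    def small(cls, **kw) -> "PhantomSpec":
        """Fast 64x96x96 preset used throughout the test suite."""
        return cls(**kw)

    @classmethod
    def fullsize(cls, **kw) -> "PhantomSpec":
        """Acquisition-scale preset: 250 axial slices of 333x333 voxels
        at 0.3 mm isotropic spacing."""
        kw.setdefault("shape", (250, 333, 333))
        kw.setdefault("electrode_radius", 4.0)
        return cls(**kw)

    # -- geometry -----------------------------------------------------------

    def base_positions(self) -> np.ndarray:
        """Mirror-symmetric electrode centres, (n, 3) in (z, y, x) voxels.

        Rows run anterior (low y) to posterior; x positions sit at
        half-integer distances from the mid-sagittal plane so that, with
        zero offsets, left and right spheres voxelise as exact mirror
        images.  Ordered anterior-to-posterior then left-to-right to
        match electrode labelling.
        """
        nz, ny, nx = self.shape
        xc = (nx - 1) / 2.0
        sy = ny / 12.0
        y0 = 2.2 * sy
        pts = []
        for r, w in enumerate(self.electrodes_per_row):
            y = y0 + r * sy
            z = 0.62 * nz - 2.0 * np.cos(np.pi * r / (len(self.electrodes_per_row) - 1))
            half = w // 2
            dists = (np.arange(half) + 0.5) * (nx / 10.7)
            for d in dists[::-1]:
                pts.append((z, y, xc - d))
            if w % 2:
                pts.append((z, y, xc))
            for d in dists:
                pts.append((z, y, xc + d))
        return np.array(pts)

    @property
    def plane_x(self) -> float:
        """True mid-sagittal plane coordinate (x, voxels)."""
        return (self.shape[2] - 1) / 2.0


def planted_offsets(
    spec: PhantomSpec, mean_mag: float, sd_mag: float, seed: int = 0,
    side: str = "left",
) -> np.ndarray:
    """Random per-electrode displacement field for one side of the palate.

    Magnitudes are |Normal(mean_mag, sd_mag)| voxels in uniformly random
    3-D directions, applied to the chosen side's electrodes only (the
    other side keeps zero offset), so the planted mirror distance of each
    affected pair equals the offset magnitude.
    """
    rng = np.random.default_rng(seed)
    base = spec.base_positions()
    n = len(base)
    out = np.zeros((n, 3))
    positions = base.copy()
    on_side = base[:, 2] < spec.plane_x if side == "left" else base[:, 2] > spec.plane_x
    idx = np.flatnonzero(on_side)
    mags = np.abs(rng.normal(mean_mag, sd_mag, size=len(idx)))
    min_gap = 2.0 * spec.electrode_radius + 1.0
    for k, i in enumerate(idx):
        # resample the direction (magnitude untouched) until the displaced
        # electrode stays strictly on its side with a 1-voxel margin and
        # does not collide with any other electrode
        for _ in range(1000):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = base[i] + mags[k] * v
            gap = (spec.plane_x - cand[2]) if side == "left" else (cand[2] - spec.plane_x)
            others = np.delete(positions, i, axis=0)
            if gap >= 1.0 and np.linalg.norm(others - cand, axis=1).min() > min_gap:
                out[i] = mags[k] * v
                positions[i] = cand
                break
        else:
            raise ValueError(
                f"offset magnitude {mags[k]:.2f} too large for electrode {i + 1}"
            )
    return out


def _paint_ball(vol: np.ndarray, centre: np.ndarray, radius: float, value: float) -> None:
    zc, yc, xc = centre
    lo = np.maximum(np.floor([zc - radius, yc - radius, xc - radius]).astype(int), 0)
    hi = np.minimum(
        np.ceil([zc + radius, yc + radius, xc + radius]).astype(int) + 1, vol.shape
    )
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    inside = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= radius**2
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][inside] = value


def build_phantom(spec: PhantomSpec) -> tuple[CTVolume, ElectrodeSet]:
    """Render the phantom volume and return it with the ground truth.

    Returns
    -------
    (CTVolume, ElectrodeSet)
        The noisy intensity volume and the *intended* electrode centres
        (base positions plus planted offsets) with sides assigned from
        the true mid-sagittal plane — the reference against which the
        segmentation pipeline's recovery is judged.

    Raises
    ------
    ValueError
        If two (offset) electrodes overlap.
    """
    nz, ny, nx = spec.shape
    centres = spec.base_positions()
    if spec.offsets is not None:
        offsets = np.asarray(spec.offsets, dtype=float)
        if offsets.shape != centres.shape:
            raise ValueError(
                f"offsets shape {offsets.shape} != ({len(centres)}, 3)"
            )
        centres = centres + offsets
    d = np.linalg.norm(centres[:, None] - centres[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 2 * spec.electrode_radius:
        i, j = np.unravel_index(d.argmin(), d.shape)
        raise ValueError(f"electrodes {i + 1} and {j + 1} overlap (gap {d.min():.2f} vox)")

    vol = np.full(spec.shape, spec.background_intensity)

    # Cast: a dome-profiled slab in the lower third of the volume, with a
    # small internal air pocket (filled by refinement) for realism.
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    dome = 0.34 * nz - 4.0 * ((xx - (nx - 1) / 2) ** 2 + (yy - ny / 2) ** 2) / (
        (nx / 2) ** 2
    )
    cast_region = (zz >= 0.1 * nz) & (zz <= dome) & (yy > 0.08 * ny) & (yy < 0.92 * ny)
    vol[cast_region] = spec.cast_intensity
    pocket = (
        (zz - 0.2 * nz) ** 2 + (yy - 0.5 * ny) ** 2 + (xx - 0.3 * nx) ** 2
    ) <= 2.0**2
    vol[pocket & cast_region] = spec.background_intensity

    # Wires: two long tubes along y, well above the electrodes.
    wire_z, wire_x = 0.85 * nz, (0.12 * nx, 0.88 * nx)
    tube_r = 2.0
    for wx in wire_x:
        tube = ((zz - wire_z) ** 2 + (xx - wx) ** 2 <= tube_r**2) & (
            (yy > 0.1 * ny) & (yy < 0.9 * ny)
        )
        vol[tube] = spec.metal_intensity

    for c in centres:
        _paint_ball(vol, c, spec.electrode_radius, spec.metal_intensity)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    spacing = (spec.spacing,) * 3
    truth = ElectrodeSet(
        electrodes=[
            Electrode(
                id=i + 1,
                centroid_vox=tuple(c),
                centroid_mm=tuple(c * spec.spacing),
                volume=0,
                side="left" if c[2] < spec.plane_x else
                ("right" if c[2] > spec.plane_x else None),
            )
            for i, c in enumerate(centres)
        ],
        spacing=spacing,
    )
    return CTVolume(vol, spacing), truth
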