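"""Palatograms: electrode layouts, binary contact frames, and asymmetry.

An electropalatography (EPG) palate carries a grid of electrodes; each
recorded frame (a *palatogram*) is a binary map of which electrodes the
tongue touched.  Asymmetry refers to an electrode being active while the
electrode at its left-right mirror position is not.  Two scalar metrics
quantify it per frame (or per accumulated map):

(a) the left and right activation counts each divided by the total number
    of activations — 0.5/0.5 when perfectly symmetric, 1/0 or 0/1 when
    fully one-sided (the two values always sum to 1);
(b) a single signed index, (right activations - left activations) /
    (right activations + left activations) — 0 when symmetric, +/-1 when
    fully one-sided.

Both are undefined for a frame with no activations and are then flagged,
never silently reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PalateLayout",
    "PalatogramFrame",
    "PalatogramSequence",
    "AsymmetryMetrics",
    "INACTIVE",
    "SYMMETRIC",
    "LEFT_ONLY",
    "RIGHT_ONLY",
    "STATE_NAMES",
    "asymmetry_map",
    "frame_metrics",
    "metrics_from_counts",
    "cumulative_activation",
    "cumulative_asymmetric_activation",
    "read_epg",
    "write_epg",
    "montage",
    "render_asymmetry_rgb",
]

# Asymmetry-map state codes.
INACTIVE, SYMMETRIC, LEFT_ONLY, RIGHT_ONLY = 0, 1, 2, 3
STATE_NAMES = {INACTIVE: "inactive", SYMMETRIC: "symmetric",
               LEFT_ONLY: "left_only", RIGHT_ONLY: "right_only"}

_EPG_MAGIC = b"EPG1"


class PalateLayout:
    """Geometry of an EPG electrode grid.

    Rows are numbered from the anterior (front) of the palate; each row has
    a declared electrode count and is centred on the palate midline.  The
    mirror partner of an electrode is the electrode at the reflected column
    within the same row; electrodes exactly on the midline (odd row widths)
    have no side.

    Parameters
    ----------
    electrodes_per_row : sequence of int
        Electrode count per row, anterior first.
    name : str
        Identifier used in file headers and figures.

    Notes
    -----
    Frames are stored as ``(n_rows, max_width)`` arrays; positions outside
    a row's extent are invalid and always zero.  Column index increases
    from the speaker's left to right, so the low-column half of each row is
    the left side.
    """

    def __init__(self, electrodes_per_row: Sequence[int], name: str = "custom"):
        widths = [int(w) for w in electrodes_per_row]
        if not widths or any(w < 1 for w in widths):
            raise ValueError("every row needs at least one electrode")
        self.name = name
        self.electrodes_per_row = widths
        self.n_rows = len(widths)
        self.max_width = max(widths)
        self.valid = np.zeros((self.n_rows, self.max_width), dtype=bool)
        self.side = np.zeros((self.n_rows, self.max_width), dtype=np.int8)
        self.mirror_col = np.full((self.n_rows, self.max_width), -1, dtype=np.int64)
        for r, w in enumerate(widths):
            off = (self.max_width - w) // 2
            cols = np.arange(off, off + w)
            self.valid[r, cols] = True
            local = cols - off
            self.side[r, cols] = np.where(
                local < w / 2 - 0.5, -1, np.where(local > w / 2 - 0.5, 1, 0)
            )
            self.mirror_col[r, cols] = off + (w - 1) - local
        self.n_electrodes = int(self.valid.sum())
        # Row-major (anterior-first) flat ordering of valid positions,
        # used by the .epg bit packing.
        self.positions: list[tuple[int, int]] = [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.max_width)
            if self.valid[r, c]
        ]

    @classmethod
    def reading62(cls) -> "PalateLayout":
        """The standard Reading-style 62-electrode palate.

        Eight rows: 6 electrodes in the anterior row, 8 in each of the
        remaining seven (the layout used by the MOCHA TIMIT recordings).
        """
        return cls([6, 8, 8, 8, 8, 8, 8, 8], name="reading62")

    @property
    def frame_bytes(self) -> int:
        """Bytes per frame in the packed binary dialect."""
        return math.ceil(self.n_electrodes / 8)

    def validate_frame(self, activation: np.ndarray) -> np.ndarray:
        act = np.asarray(activation)
        if act.shape != (self.n_rows, self.max_width):
            raise ValueError(
                f"frame shape {act.shape} does not match layout "
                f"({self.n_rows}, {self.max_width})"
            )
        act = (act != 0).astype(np.uint8)
        if np.any(act[~self.valid]):
            raise ValueError("activation outside the layout's electrode positions")
        return act

    def flip_lr(self, activation: np.ndarray) -> np.ndarray:
        """Left-right mirror of a frame (each electrode moved to its partner)."""
        act = self.validate_frame(activation)
        out = np.zeros_like(act)
        rr, cc = np.nonzero(self.valid)
        out[rr, self.mirror_col[rr, cc]] = act[rr, cc]
        return out

    def flat(self, activation: np.ndarray) -> np.ndarray:
        """Row-major vector of the valid positions (length n_electrodes)."""
        act = self.validate_frame(activation)
        return act[self.valid]

    def unflat(self, bits: np.ndarray) -> np.ndarray:
        bits = np.asarray(bits).ravel()
        if bits.size != self.n_electrodes:
            raise ValueError(
                f"expected {self.n_electrodes} values, got {bits.size}"
            )
        out = np.zeros((self.n_rows, self.max_width), dtype=np.uint8)
        out[self.valid] = (bits != 0).astype(np.uint8)
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PalateLayout)
            and self.electrodes_per_row == other.electrodes_per_row
        )

    def __repr__(self) -> str:
        return f"PalateLayout({self.electrodes_per_row!r}, name={self.name!r})"


@dataclass
class PalatogramFrame:
    """One binary tongue-palate contact snapshot on a layout."""

    activation: np.ndarray
    layout: PalateLayout
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.activation = self.layout.validate_frame(self.activation)

    @property
    def n_active(self) -> int:
        return int(self.activation.sum())


@dataclass
class PalatogramSequence:
    """A time series of palatogram frames sharing one layout.

    ``frames`` is stored as a single ``(n_frames, n_rows, max_width)``
    uint8 array; ``frame_rate`` is in Hz.
    """

    frames: np.ndarray
    frame_rate: float
    layout: PalateLayout

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[1:] != (
            self.layout.n_rows,
            self.layout.max_width,
        ):
            raise ValueError("frames must be (n_frames, n_rows, max_width)")
        frames = (frames != 0).astype(np.uint8)
        if np.any(frames[:, ~self.layout.valid]):
            raise ValueError("activation outside the layout's electrode positions")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def frame(self, i: int) -> PalatogramFrame:
        return PalatogramFrame(self.frames[i], self.layout, frame_index=i)

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class AsymmetryMetrics:
    """The two per-frame asymmetry metrics.

    ``n_left``/``n_right`` count all active electrodes on each side
    (midline electrodes, when a layout has them, belong to neither count).
    When nothing is active the metrics are undefined: ``defined`` is False
    and the fractions/index are NaN.
    """

    n_left: int
    n_right: int

    @property
    def defined(self) -> bool:
        return (self.n_left + self.n_right) > 0

    @property
    def left_fraction(self) -> float:
        t = self.n_left + self.n_right
        return self.n_left / t if t else float("nan")

    @property
    def right_fraction(self) -> float:
        t = self.n_left + self.n_right
        return self.n_right / t if t else float("nan")

    @property
    def signed_index(self) -> float:
        t = self.n_left + self.n_right
        return (self.n_right - self.n_left) / t if t else float("nan")


def asymmetry_map(frame: PalatogramFrame) -> np.ndarray:
    """Classify each electrode of a frame by its mirror relationship.

    Returns an ``(n_rows, max_width)`` int8 array of state codes: an active
    electrode is ``SYMMETRIC`` iff its mirror partner is also active, else
    ``LEFT_ONLY``/``RIGHT_ONLY`` according to its side; everything else is
    ``INACTIVE``.  Midline electrodes are symmetric with themselves and
    therefore always ``SYMMETRIC`` when active.
    """
    lay = frame.layout
    act = frame.activation
    mirrored = lay.flip_lr(act)
    out = np.zeros(act.shape, dtype=np.int8)
    both = (act == 1) & (mirrored == 1)
    only = (act == 1) & (mirrored == 0)
    out[both] = SYMMETRIC
    out[only & (lay.side < 0)] = LEFT_ONLY
    out[only & (lay.side > 0)] = RIGHT_ONLY
    return out


def frame_metrics(frame: PalatogramFrame) -> AsymmetryMetrics:
    """Compute both asymmetry metrics for one frame."""
    act = frame.activation
    side = frame.layout.side
    return AsymmetryMetrics(
        n_left=int(act[side < 0].sum()),
        n_right=int(act[side > 0].sum()),
    )


def metrics_from_counts(count_map: np.ndarray, layout: PalateLayout) -> AsymmetryMetrics:
    """Asymmetry metrics of an accumulated (non-binary) activation map."""
    counts = np.asarray(count_map)
    if counts.shape != (layout.n_rows, layout.max_width):
        raise ValueError("count map shape does not match layout")
    return AsymmetryMetrics(
        n_left=int(counts[layout.side < 0].sum()),
        n_right=int(counts[layout.side > 0].sum()),
    )


def _resolve_range(seq: PalatogramSequence, frame_range: tuple[int, int] | None):
    if frame_range is None:
        return 0, seq.n_frames
    a, b = frame_range
    if a < 0 or b > seq.n_frames or a > b:
        raise ValueError(
            f"frame range [{a}, {b}) outside sequence of {seq.n_frames} frames"
        )
    return a, b


def cumulative_activation(
    seq: PalatogramSequence, frame_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-electrode activation counts over ``frame_range`` (half-open).

    The count increases by one for every frame in which the electrode is
    active, producing the total-activation map of a sentence or phoneme.
    An empty range yields an all-zero map.
    """
    a, b = _resolve_range(seq, frame_range)
    return seq.frames[a:b].sum(axis=0, dtype=np.int64)


def cumulative_asymmetric_activation(
    seq: PalatogramSequence, frame_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-electrode counts of *asymmetric* activations over a range.

    An activation is counted only when the electrode's mirror partner is
    inactive in the same frame, so a perfectly mirror-symmetric sequence
    accumulates nothing.
    """
    a, b = _resolve_range(seq, frame_range)
    lay = seq.layout
    out = np.zeros((lay.n_rows, lay.max_width), dtype=np.int64)
    rr, cc = np.nonzero(lay.valid)
    sub = seq.frames[a:b]
    mirrored = np.zeros_like(sub)
    mirrored[:, rr, lay.mirror_col[rr, cc]] = sub[:, rr, cc]
    out += ((sub == 1) & (mirrored == 0)).sum(axis=0, dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# .epg file dialects
# ---------------------------------------------------------------------------

def write_epg(seq: PalatogramSequence, path: str | Path, text: bool = False) -> None:
    """Write a palatogram sequence in the package's ``.epg`` dialect.

    Binary dialect (default): 4-byte magic ``EPG1``, one ASCII line with
    the frame rate in Hz, then per frame ``ceil(n_electrodes/8)`` bytes of
    activation bits packed row-major anterior-first, most-significant bit
    first.  Text dialect: one ``0``/``1`` string of length ``n_electrodes``
    per line, same bit order.
    """
    path = Path(path)
    lay = seq.layout
    flat = seq.frames[:, lay.valid]  # (n_frames, n_electrodes)
    if text:
        with open(path, "w", encoding="ascii") as fh:
            for row in flat:
                fh.write("".join("1" if b else "0" for b in row) + "\n")
        return
    payload = np.packbits(flat, axis=1) if flat.size else np.zeros((0, 0), np.uint8)
    with open(path, "wb") as fh:
        fh.write(_EPG_MAGIC)
        fh.write(f"{seq.frame_rate:g}\n".encode("ascii"))
        fh.write(payload.tobytes())


def read_epg(
    path: str | Path,
    layout: PalateLayout | None = None,
    frame_rate: float | None = None,
) -> PalatogramSequence:
    """Read an ``.epg`` file (binary or text dialect, auto-detected).

    Parameters
    ----------
    layout : PalateLayout, optional
        Defaults to the Reading-style 62-electrode palate.
    frame_rate : float, optional
        Overrides the rate stored in a binary file; required context for
        text files (defaults to 200 Hz, the standard EPG3 hardware rate).

    Raises
    ------
    ValueError
        If the payload is not a whole number of frames; the message
        reports the offending byte offset.
    """
    path = Path(path)
    lay = layout or PalateLayout.reading62()
    raw = path.read_bytes()
    if raw[:4] == _EPG_MAGIC:
        nl = raw.index(b"\n", 4)
        stored_rate = float(raw[4:nl].decode("ascii"))
        payload = raw[nl + 1:]
        fb = lay.frame_bytes
        if len(payload) % fb:
            raise ValueError(
                f"{path.name}: trailing partial frame at byte offset "
                f"{nl + 1 + (len(payload) // fb) * fb} "
                f"({len(payload) % fb} of {fb} bytes)"
            )
        n_frames = len(payload) // fb
        bits = np.unpackbits(
            np.frombuffer(payload, dtype=np.uint8).reshape(n_frames, fb), axis=1
        )[:, : lay.n_electrodes]
        rate = frame_rate if frame_rate is not None else stored_rate
    else:
        lines = [
            ln.strip()
            for ln in raw.decode("ascii").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        for i, ln in enumerate(lines):
            if len(ln) != lay.n_electrodes or set(ln) - {"0", "1"}:
                raise ValueError(
                    f"{path.name}: line {i + 1} is not a {lay.n_electrodes}-bit 0/1 string"
                )
        bits = np.array(
            [[int(ch) for ch in ln] for ln in lines], dtype=np.uint8
        ).reshape(len(lines), lay.n_electrodes)
        rate = frame_rate if frame_rate is not None else 200.0
    frames = np.zeros((bits.shape[0], lay.n_rows, lay.max_width), dtype=np.uint8)
    frames[:, lay.valid] = bits
    return PalatogramSequence(frames=frames, frame_rate=rate, layout=lay)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# Fig-5-style colours: white = symmetric, cyan = left-only, pink = right-only.
_STATE_RGB = np.array(
    [
        [0.25, 0.25, 0.25],  # inactive
        [1.00, 1.00, 1.00],  # symmetric
        [0.00, 0.85, 0.95],  # left only (cyan)
        [1.00, 0.45, 0.70],  # right only (pink)
    ]
)
_INVALID_RGB = np.array([0.08, 0.08, 0.08])


def render_asymmetry_rgb(frame: PalatogramFrame) -> np.ndarray:
    """RGB image of a frame's asymmetry map (anterior row at the top)."""
    states = asymmetry_map(frame)
    img = _STATE_RGB[states]
    img[~frame.layout.valid] = _INVALID_RGB
    return img


def montage(
    seq: PalatogramSequence,
    frame_range: tuple[int, int] | None = None,
    n_cols: int | None = None,
    ax=None,
):
    """Tile the asymmetry maps of a frame range into one image.

    A montage makes the evolution of asymmetry over a sentence visible at
    a glance.  Raises on an empty range.
    """
    import matplotlib.pyplot as plt

    a, b = _resolve_range(seq, frame_range)
    n = b - a
    if n == 0:
        raise ValueError("montage of an empty frame range")
    if n_cols is None:
        n_cols = int(math.ceil(math.sqrt(n)))
    n_rows_m = int(math.ceil(n / n_cols))
    lay = seq.layout
    h, w = lay.n_rows + 1, lay.max_width + 1  # 1-pixel separator
    canvas = np.zeros((n_rows_m * h, n_cols * w, 3))
    for k in range(n):
        tile = render_asymmetry_rgb(seq.frame(a + k))
        r, c = divmod(k, n_cols)
        canvas[r * h : r * h + lay.n_rows, c * w : c * w + lay.max_width] = tile
    if ax is None:
        _, ax = plt.subplots(figsize=(min(12, n_cols), min(12, n_rows_m)))
    ax.imshow(canvas, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
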