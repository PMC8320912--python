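"""Phoneme annotation formats: MOCHA-style ``.lab`` files and Praat TextGrids.

A ``.lab`` file records one phoneme per line as ``start end label`` (times
in seconds).  Praat TextGrids store the same information as interval tiers
in a self-describing text format.  This module reads both, writes long-form
TextGrids, and batch-converts ``.lab`` files so that MOCHA-style corpora
can be inspected in Praat.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PhonemeInterval",
    "PhonemeTimeline",
    "LabParseError",
    "TextGridParseError",
    "read_lab",
    "write_textgrid",
    "read_textgrid",
    "convert",
]


class LabParseError(ValueError):
    """Raised for malformed ``.lab`` content; message names the line."""


class TextGridParseError(ValueError):
    """Raised for TextGrid files that are not valid long-form text."""


@dataclass(frozen=True)
class PhonemeInterval:
    """A labelled time interval: one phoneme (or word) occurrence.

    Parameters
    ----------
    label : str
        Phoneme (or word) code, e.g. ``"dh"``, ``"s"``, ``"sil"``.
    start, end : float
        Interval boundaries in seconds; ``end`` must exceed ``start``.
    """

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("interval label must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start time {self.start!r}")
        if not self.end > self.start:
            raise ValueError(
                f"interval end {self.end!r} must exceed start {self.start!r}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


def _check_tier(intervals: Sequence[PhonemeInterval], name: str) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.start:
            raise ValueError(f"{name} tier not sorted by start time")
        if b.start < a.end - 1e-9:
            raise ValueError(
                f"{name} tier has overlapping intervals "
                f"({a.label!r} [{a.start}, {a.end}] and {b.label!r} [{b.start}, {b.end}])"
            )


@dataclass
class PhonemeTimeline:
    """Ordered phoneme intervals for one utterance, with an optional word tier.

    Intervals within a tier must be sorted and non-overlapping (touching
    endpoints are allowed); ``total_duration`` defaults to the latest
    interval end over both tiers.
    """

    phonemes: list[PhonemeInterval] = field(default_factory=list)
    words: list[PhonemeInterval] | None = None
    total_duration: float = 0.0

    def __post_init__(self) -> None:
        _check_tier(self.phonemes, "phoneme")
        if self.words is not None:
            _check_tier(self.words, "word")
        last = 0.0
        for tier in (self.phonemes, self.words or []):
            for iv in tier:
                last = max(last, iv.end)
        if self.total_duration < last:
            self.total_duration = last

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhonemeTimeline):
            return NotImplemented
        return (
            self._tier_eq(self.phonemes, other.phonemes)
            and self._tier_eq(self.words or [], other.words or [])
            and abs(self.total_duration - other.total_duration) <= 1e-6
        )

    @staticmethod
    def _tier_eq(a: Sequence[PhonemeInterval], b: Sequence[PhonemeInterval]) -> bool:
        if len(a) != len(b):
            return False
        return all(
            x.label == y.label
            and abs(x.start - y.start) <= 1e-6
            and abs(x.end - y.end) <= 1e-6
            for x, y in zip(a, b)
        )


def read_lab(path: str | Path, columns: int = 3) -> PhonemeTimeline:
    """Read a MOCHA-style ``.lab`` phoneme label file.

    Each non-empty line carries whitespace-separated fields; lines starting
    with ``#`` are ignored.  With ``columns=3`` (the default) the fields are
    ``start end label``; with ``columns=2`` they are ``end label`` and each
    interval starts where the previous one ended (the first at 0).

    Parameters
    ----------
    path : path-like
        File to read.
    columns : {3, 2}
        Field layout of the file.

    Returns
    -------
    PhonemeTimeline
        One interval per line, in file order.  Silence/breath labels are
        kept as ordinary intervals.

    Raises
    ------
    LabParseError
        On non-numeric times, ``end <= start``, or too few fields; the
        message cites the 1-based line number.
    """
    if columns not in (2, 3):
        raise ValueError(f"columns must be 2 or 3, got {columns}")
    path = Path(path)
    intervals: list[PhonemeInterval] = []
    prev_end = 0.0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < columns:
                raise LabParseError(
                    f"{path.name}:{lineno}: expected at least {columns} fields, "
                    f"got {len(fields)}"
                )
            try:
                if columns == 3:
                    start, end = float(fields[0]), float(fields[1])
                    label = " ".join(fields[2:])
                else:
                    start, end = prev_end, float(fields[0])
                    label = " ".join(fields[1:])
            except ValueError as exc:
                raise LabParseError(f"{path.name}:{lineno}: non-numeric time ({exc})") from None
            if end <= start:
                raise LabParseError(
                    f"{path.name}:{lineno}: end time {end} not after start {start}"
                )
            intervals.append(PhonemeInterval(label, start, end))
            prev_end = end
    return PhonemeTimeline(phonemes=intervals)


def _fmt(x: float) -> str:
    # repr keeps round trips exact; strip the trailing ".0" Praat also omits
    return format(float(x), ".17g")


def _tile(intervals: Sequence[PhonemeInterval], xmax: float) -> list[tuple[float, float, str]]:
    """Fill gaps with empty-label intervals so the tier tiles [0, xmax]."""
    out: list[tuple[float, float, str]] = []
    cursor = 0.0
    for iv in intervals:
        if iv.start > cursor + 1e-9:
            out.append((cursor, iv.start, ""))
        out.append((iv.start, iv.end, iv.label))
        cursor = iv.end
    if xmax > cursor + 1e-9:
        out.append((cursor, xmax, ""))
    if not out:
        out.append((0.0, max(xmax, 0.0) or 1.0, ""))
    return out


def write_textgrid(timeline: PhonemeTimeline, path: str | Path) -> None:
    """Write a long-form (verbose) Praat TextGrid.

    The phoneme tier is named ``"phonemes"``; a ``"words"`` tier is added
    when the timeline carries one.  Gaps between annotated intervals are
    filled with empty-label intervals so every tier tiles
    ``[0, total_duration]`` with exactly shared boundaries.
    """
    xmax = timeline.total_duration if timeline.total_duration > 0 else 1.0
    tiers: list[tuple[str, list[tuple[float, float, str]]]] = [
        ("phonemes", _tile(timeline.phonemes, xmax))
    ]
    if timeline.words is not None:
        tiers.append(("words", _tile(timeline.words, xmax)))

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {_fmt(xmax)}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for t, (name, ivs) in enumerate(tiers, start=1):
        lines += [
            f"    item [{t}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {_fmt(xmax)}",
            f"        intervals: size = {len(ivs)}",
        ]
        for i, (a, b, label) in enumerate(ivs, start=1):
            esc = label.replace('"', '""')
            lines += [
                f"        intervals [{i}]:",
                f"            xmin = {_fmt(a)}",
                f"            xmax = {_fmt(b)}",
                f'            text = "{esc}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_textgrid(path: str | Path) -> PhonemeTimeline:
    """Read a long-form Praat TextGrid into a :class:`PhonemeTimeline`.

    The tier named ``"phonemes"`` (or, failing that, the first interval
    tier not named ``"words"``) becomes the phoneme tier; a tier named
    ``"words"`` becomes the word tier.  Empty-label padding intervals are
    dropped.

    Raises
    ------
    TextGridParseError
        For short-form or corrupt files.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if "ooTextFile" not in text.split("\n", 1)[0]:
        raise TextGridParseError(f"{path.name}: not an ooTextFile TextGrid")
    # Short-form TextGrids have no "item" / key = value structure.
    if "IntervalTier" in text and "=" not in text:
        raise TextGridParseError(f"{path.name}: short-form TextGrid not supported")

    tiers: list[dict] = []
    current: dict | None = None
    interval: dict | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("item ["):
            current = None
            continue
        m = re.match(r'^class\s*=\s*"(.*)"$', line)
        if m:
            current = {"class": m.group(1), "name": "", "intervals": []}
            tiers.append(current)
            interval = None
            continue
        if current is None:
            continue
        m = re.match(r'^name\s*=\s*"(.*)"$', line)
        if m:
            current["name"] = m.group(1).replace('""', '"')
            continue
        if line.startswith("intervals ["):
            interval = {}
            current["intervals"].append(interval)
            continue
        m = re.match(r"^(xmin|xmax)\s*=\s*([-+0-9.eE]+)$", line)
        if m and interval is not None:
            try:
                interval[m.group(1)] = float(m.group(2))
            except ValueError as exc:
                raise TextGridParseError(f"{path.name}: bad number {m.group(2)!r}") from exc
            continue
        m = re.match(r'^text\s*=\s*"(.*)"$', line)
        if m and interval is not None:
            interval["text"] = m.group(1).replace('""', '"')
            continue

    interval_tiers = [t for t in tiers if t["class"] == "IntervalTier"]
    if not interval_tiers:
        raise TextGridParseError(f"{path.name}: no interval tier found")

    def to_intervals(tier: dict) -> list[PhonemeInterval]:
        out = []
        for iv in tier["intervals"]:
            if "xmin" not in iv or "xmax" not in iv:
                raise TextGridParseError(f"{path.name}: interval missing boundaries")
            if iv.get("text", ""):
                out.append(PhonemeInterval(iv["text"], iv["xmin"], iv["xmax"]))
        return out

    words_tier = next((t for t in interval_tiers if t["name"] == "words"), None)
    phon_tier = next(
        (t for t in interval_tiers if t["name"] == "phonemes"),
        next((t for t in interval_tiers if t is not words_tier), None),
    )
    phonemes = to_intervals(phon_tier) if phon_tier else []
    words = to_intervals(words_tier) if words_tier else None
    if phonemes or words:
        xmax = max(
            (iv["xmax"] for t in interval_tiers for iv in t["intervals"] if "xmax" in iv),
            default=0.0,
        )
    else:
        xmax = 0.0  # a TextGrid with only empty-label padding annotates nothing
    return PhonemeTimeline(phonemes=phonemes, words=words, total_duration=xmax)


def convert(path_or_dir: str | Path, columns: int = 3) -> list[Path]:
    """Convert a ``.lab`` file, or every ``.lab`` file in a directory, to TextGrid.

    Each file is written as a sibling with the ``.TextGrid`` extension.

    Returns
    -------
    list of Path
        The TextGrid files written.  An empty directory yields ``[]`` with
        a warning.
    """
    path = Path(path_or_dir)
    if path.is_dir():
        sources = sorted(path.glob("*.lab"))
        if not sources:
            warnings.warn(f"no .lab files found in {path}", stacklevel=2)
    elif path.is_file():
        sources = [path]
    else:
        raise FileNotFoundError(path)
    written = []
    for src in sources:
        dst = src.with_suffix(".TextGrid")
        write_textgrid(read_lab(src, columns=columns), dst)
        written.append(dst)
    return written
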