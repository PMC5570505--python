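"""Reading, validation and writing of combed-fiber track tables.

A fiber is an ordered sequence of measured tracks, each labeled red (CldU,
first pulse), green (IdU, second pulse) or unlabeled.  The on-disk format is
a TSV with one row per track::

    dataset_id  fiber_id  track_index  label  length_kb

with ``label`` one of ``R``, ``G``, ``U`` and ``track_index`` 1-based and
strictly increasing within a fiber.  Lengths are carried in kb (3-decimal
precision); an optional ``length_px`` column is converted on read when the
dataset metadata provides a stretching factor.  Consecutive equal-label rows
are merged on read so that every in-memory fiber strictly alternates labels.
Fibers shorter than the minimum analyzable length (120 kb by default) are
retained but flagged ``excluded`` so exclusion counts stay reportable.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

# Lambda phage genome length in kb; the sizing standard for combing.
LAMBDA_KB = 48.502

#: Minimum analyzable fiber length (kb).
DEFAULT_MIN_FIBER_KB = 120.0


class Label(enum.Enum):
    """Track label: first-pulse analog, second-pulse analog, or none."""

    RED = "R"
    GREEN = "G"
    UNLABELED = "U"


@dataclass(frozen=True)
class LabelTrack:
    """A single measured track on a fiber."""

    label: Label
    length_kb: float

    def __post_init__(self) -> None:
        if not isinstance(self.label, Label):
            raise TypeError(f"label must be a Label, got {self.label!r}")
        if not self.length_kb > 0:
            raise ValueError(f"track length must be positive, got {self.length_kb}")


@dataclass(frozen=True)
class Fiber:
    """An ordered, alternating sequence of tracks from one combed molecule.

    ``excluded`` marks fibers below the minimum analyzable length; they are
    kept so that exclusion counts can be reported, but estimators skip them.
    """

    fiber_id: str
    tracks: tuple[LabelTrack, ...]
    dataset_id: str = ""
    excluded: bool = False

    def __post_init__(self) -> None:
        for a, b in zip(self.tracks, self.tracks[1:]):
            if a.label is b.label:
                raise ValueError(
                    f"fiber {self.fiber_id!r}: consecutive tracks share label "
                    f"{a.label.value}; merge equal-label neighbors first"
                )

    @property
    def total_length_kb(self) -> float:
        return sum(t.length_kb for t in self.tracks)

    @property
    def unreplicated_kb(self) -> float:
        """Total unlabeled length (conflates unreplicated and pre-pulse DNA)."""
        return sum(t.length_kb for t in self.tracks if t.label is Label.UNLABELED)

    def pattern(self) -> str:
        return "".join(t.label.value for t in self.tracks)


@dataclass(frozen=True)
class DatasetMeta:
    """Labeling-scheme and provenance metadata for one dataset."""

    pulse1_min: float = 5.0
    pulse2_min: float = 10.0
    treatment: str = "untreated"
    genotype: str = "wt"
    stretch_kb_per_pixel: float | None = None
    min_fiber_kb: float = DEFAULT_MIN_FIBER_KB

    def __post_init__(self) -> None:
        if not (self.pulse1_min > 0 and self.pulse2_min > 0):
            raise ValueError("pulse durations must be positive")

    @property
    def total_pulse_min(self) -> float:
        return self.pulse1_min + self.pulse2_min


def pixels_to_kb(length_px: float, lambda_px: float) -> float:
    """Convert a pixel measurement to kb against the lambda-DNA standard.

    ``lambda_px`` is the measured pixel length of a full lambda genome
    (48.502 kb) on the same coverslip.
    """
    if not length_px > 0:
        raise ValueError(f"length_px must be positive, got {length_px}")
    if not lambda_px > 0:
        raise ValueError(f"lambda_px must be positive, got {lambda_px}")
    return length_px * (LAMBDA_KB / lambda_px)


def merge_tracks(tracks: Iterable[LabelTrack]) -> tuple[LabelTrack, ...]:
    """Merge consecutive equal-label tracks, conserving total length."""
    merged: list[LabelTrack] = []
    for t in tracks:
        if merged and merged[-1].label is t.label:
            merged[-1] = LabelTrack(t.label, merged[-1].length_kb + t.length_kb)
        else:
            merged.append(LabelTrack(t.label, t.length_kb))
    return tuple(merged)


def make_fiber(
    fiber_id: str,
    tracks: Iterable[LabelTrack],
    dataset_id: str = "",
    min_fiber_kb: float = DEFAULT_MIN_FIBER_KB,
) -> Fiber:
    """Build a fiber, merging equal-label neighbors and applying the length flag."""
    merged = merge_tracks(tracks)
    total = sum(t.length_kb for t in merged)
    return Fiber(
        fiber_id=fiber_id,
        tracks=merged,
        dataset_id=dataset_id,
        excluded=total < min_fiber_kb,
    )


class FiberTableError(ValueError):
    """Malformed fiber table; the message names the offending line."""


_COLUMNS = ["dataset_id", "fiber_id", "track_index", "label", "length_kb"]


def read_fiber_table(path: str | Path | io.TextIOBase, meta: DatasetMeta | None = None) -> list[Fiber]:
    """Read a fiber track table (TSV) into validated :class:`Fiber` objects.

    Equal-label neighbors are merged; fibers shorter than
    ``meta.min_fiber_kb`` are flagged ``excluded`` rather than dropped.
    Track order within each fiber follows ``track_index``; fiber order
    follows first appearance in the file.
    """
    meta = meta or DatasetMeta()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "length_kb"]
    has_kb = "length_kb" in df.columns
    has_px = "length_px" in df.columns
    if missing or not (has_kb or has_px):
        raise FiberTableError(
            f"fiber table must have columns {_COLUMNS} (or length_px); "
            f"got {list(df.columns)}"
        )
    if has_px and not has_kb and meta.stretch_kb_per_pixel is None:
        raise FiberTableError(
            "table carries length_px only but meta.stretch_kb_per_pixel is unset"
        )

    rows_by_fiber: dict[tuple[str, str], list[tuple[int, LabelTrack]]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        rec = row._asdict()
        try:
            idx = int(rec["track_index"])
        except ValueError:
            raise FiberTableError(f"line {line_no}: bad track_index {rec['track_index']!r}") from None
        code = rec["label"].strip().upper()
        try:
            label = Label(code)
        except ValueError:
            raise FiberTableError(f"line {line_no}: unknown label code {rec['label']!r}") from None
        raw = rec.get("length_kb", "")
        try:
            if has_kb and raw != "":
                length = float(raw)
            else:
                length = float(rec["length_px"]) * float(meta.stretch_kb_per_pixel)
        except (ValueError, TypeError):
            raise FiberTableError(f"line {line_no}: unparsable length in {rec!r}") from None
        if not length > 0:
            raise FiberTableError(f"line {line_no}: non-positive track length {length}")
        key = (rec["dataset_id"], rec["fiber_id"])
        bucket = rows_by_fiber.setdefault(key, [])
        if bucket and idx <= bucket[-1][0]:
            raise FiberTableError(
                f"line {line_no}: track_index {idx} not strictly increasing within fiber {key[1]!r}"
            )
        bucket.append((idx, LabelTrack(label, round(length, 3))))

    fibers = []
    for (dataset_id, fiber_id), rows in rows_by_fiber.items():
        fibers.append(
            make_fiber(
                fiber_id,
                [t for _, t in rows],
                dataset_id=dataset_id,
                min_fiber_kb=meta.min_fiber_kb,
            )
        )
    return fibers


def write_fiber_table(fibers: Sequence[Fiber], path: str | Path | io.TextIOBase) -> None:
    """Write fibers in the TSV dialect read by :func:`read_fiber_table`."""
    records = []
    for f in fibers:
        for i, t in enumerate(f.tracks, start=1):
            records.append(
                {
                    "dataset_id": f.dataset_id,
                    "fiber_id": f.fiber_id,
                    "track_index": i,
                    "label": t.label.value,
                    "length_kb": f"{t.length_kb:.3f}",
                }
            )
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dataset_meta(path: str | Path) -> DatasetMeta:
    """Load dataset metadata from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DatasetMeta(**raw)


def write_dataset_meta(meta: DatasetMeta, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "pulse1_min": meta.pulse1_min,
                "pulse2_min": meta.pulse2_min,
                "treatment": meta.treatment,
                "genotype": meta.genotype,
                "stretch_kb_per_pixel": meta.stretch_kb_per_pixel,
                "min_fiber_kb": meta.min_fiber_kb,
            },
            fh,
            sort_keys=False,
        )
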