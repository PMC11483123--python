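"""Movie, ROI and protocol I/O plus the shared clock and coordinate conventions.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, pixel centers at integer
  coordinates;
* time is in seconds from the first frame; frame ``k`` at rate ``f`` covers
  the half-open interval ``[k/f, (k+1)/f)``;
* all epoch intervals are half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "MovieStack",
    "EpochTimeline",
    "Epoch",
    "StimulationProtocol",
    "RoiBox",
    "read_movie",
    "write_movie",
    "build_timeline",
    "read_roi_table",
    "write_roi_table",
    "write_results",
    "read_protocol",
]

EPOCH_KINDS = (
    "baseline",
    "stim_train",
    "inter_train",
    "inter_burst",
    "post_stim",
    "nh4",
    "bleach",
)


@dataclass(frozen=True)
class MovieStack:
    """A single-channel fluorescence time-lapse.

    Parameters
    ----------
    data
        Intensity array indexed ``(frame, row, col)``, arbitrary camera units.
    frame_rate_hz
        Acquisitions per second (EMCCD live imaging default: 2 Hz).
    pixel_size_um
        Micrometres per pixel (default 0.2 um, i.e. 200 nm).
    channel
        Free-text channel label.
    origin_s
        Acquisition start time in seconds; defines t = 0.
    """

    data: np.ndarray
    frame_rate_hz: float = 2.0
    pixel_size_um: float = 0.2
    channel: str = ""
    origin_s: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"movie must be (frame, row, col); got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("frame count >= 2 required")
        if not np.all(np.isfinite(data)):
            raise ValueError("movie contains non-finite intensities")
        if data.min() < 0:
            raise ValueError("movie contains negative intensities")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_rc(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        """Start time of each frame (frame k covers [k/f, (k+1)/f))."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def time_to_frame(self, t_s: float) -> int:
        return int(np.floor(t_s * self.frame_rate_hz))


@dataclass(frozen=True)
class Epoch:
    kind: str
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if not self.t_end_s > self.t_start_s:
            raise ValueError("epoch must have positive duration")

    def contains(self, t_s: float) -> bool:
        return self.t_start_s <= t_s < self.t_end_s


@dataclass(frozen=True)
class EpochTimeline:
    """Ordered, typed intervals (baseline, stim trains, NH4+, bleach ...) on the movie clock."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        epochs = tuple(sorted(self.epochs, key=lambda e: (e.t_start_s, e.t_end_s)))
        by_kind: dict[str, list[Epoch]] = {}
        for e in epochs:
            by_kind.setdefault(e.kind, []).append(e)
        for kind, same in by_kind.items():
            for a, b in zip(same, same[1:]):
                if b.t_start_s < a.t_end_s:
                    raise ValueError(f"overlapping {kind} epochs: {a} / {b}")
        object.__setattr__(self, "epochs", epochs)

    def of_kind(self, kind: str) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.kind == kind)

    def kinds_at(self, t_s: float) -> tuple[str, ...]:
        return tuple(e.kind for e in self.epochs if e.contains(t_s))

    def in_kind(self, t_s: float | np.ndarray, kind: str) -> np.ndarray | bool:
        """Whether time(s) fall inside any epoch of the given kind."""
        t = np.asarray(t_s, dtype=float)
        hit = np.zeros(t.shape, dtype=bool)
        for e in self.of_kind(kind):
            hit |= (t >= e.t_start_s) & (t < e.t_end_s)
        return hit if t.ndim else bool(hit)

    def frame_mask(self, kind: str, n_frames: int, frame_rate_hz: float) -> np.ndarray:
        """Boolean mask over frames whose start time lies in an epoch of `kind`."""
        return np.asarray(self.in_kind(np.arange(n_frames) / frame_rate_hz, kind))

    @property
    def t_first_train_s(self) -> float | None:
        trains = self.of_kind("stim_train")
        return trains[0].t_start_s if trains else None

    @property
    def t_last_train_end_s(self) -> float | None:
        trains = self.of_kind("stim_train")
        return trains[-1].t_end_s if trains else None


@dataclass(frozen=True)
class StimulationProtocol:
    """Electrical stimulation paradigm: bursts of AP trains at fixed frequency.

    The live-imaging paradigms are e.g. two bursts of 8 trains of 50 APs at
    50 Hz (0.5 s between trains, 30 s between bursts) or one burst of 16
    such trains, delivered after 30 s of baseline.
    """

    n_bursts: int = 2
    trains_per_burst: int = 8
    aps_per_train: int = 50
    ap_rate_hz: float = 50.0
    inter_train_s: float = 0.5
    inter_burst_s: float = 30.0
    t_first_train_s: float = 30.0

    def __post_init__(self) -> None:
        if min(self.n_bursts, self.trains_per_burst, self.aps_per_train) < 1:
            raise ValueError("all counts must be >= 1")
        if min(self.ap_rate_hz, self.inter_train_s, self.inter_burst_s) <= 0:
            raise ValueError("rates and gaps must be > 0")

    @property
    def train_duration_s(self) -> float:
        return self.aps_per_train / self.ap_rate_hz

    @property
    def burst_duration_s(self) -> float:
        n = self.trains_per_burst
        return n * self.train_duration_s + (n - 1) * self.inter_train_s

    @property
    def t_last_train_end_s(self) -> float:
        return (
            self.t_first_train_s
            + self.n_bursts * self.burst_duration_s
            + (self.n_bursts - 1) * self.inter_burst_s
        )

    def train_intervals(self) -> list[tuple[float, float]]:
        out = []
        for b in range(self.n_bursts):
            t = self.t_first_train_s + b * (self.burst_duration_s + self.inter_burst_s)
            for _ in range(self.trains_per_burst):
                out.append((t, t + self.train_duration_s))
                t += self.train_duration_s + self.inter_train_s
        return out


@dataclass(frozen=True)
class RoiBox:
    """Square ROI: a (2*half_width+1)^2 pixel box around an integer center.

    The fusion assay uses 3x3 pixel ROIs, i.e. ``half_width_px=1``.
    """

    center_rc: tuple[int, int]
    half_width_px: int = 1
    roi_id: int = 0

    def __post_init__(self) -> None:
        if self.half_width_px < 0:
            raise ValueError("half_width_px must be >= 0")

    def slices(self) -> tuple[slice, slice]:
        r, c = self.center_rc
        h = self.half_width_px
        return slice(r - h, r + h + 1), slice(c - h, c + h + 1)

    def inside(self, shape_rc: tuple[int, int]) -> bool:
        r, c = self.center_rc
        h = self.half_width_px
        return r - h >= 0 and c - h >= 0 and r + h < shape_rc[0] and c + h < shape_rc[1]


# ---------------------------------------------------------------------------
# movie I/O


def read_movie(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
    channel: str = "",
) -> MovieStack:
    """Read a TIFF / OME-TIFF stack as a :class:`MovieStack`.

    OME metadata, when present, takes precedence over the supplied
    ``frame_rate_hz`` / ``pixel_size_um``; one of the two sources must
    provide each quantity.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome_px, ome_dt = _ome_calibration(tf)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) stack; got shape {data.shape}")
    px = ome_px if ome_px is not None else pixel_size_um
    fr = ome_dt if ome_dt is not None else frame_rate_hz
    if px is None or fr is None:
        raise ValueError("frame rate and pixel size missing from both file and metadata")
    return MovieStack(np.asarray(data, dtype=float), frame_rate_hz=fr,
                      pixel_size_um=px, channel=channel)


def _ome_calibration(tf: "tifffile.TiffFile") -> tuple[float | None, float | None]:
    """Extract (pixel_size_um, frame_rate_hz) from OME-XML if available."""
    if not tf.is_ome or tf.ome_metadata is None:
        return None, None
    import re

    xml = tf.ome_metadata
    px = None
    fr = None
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', xml)
    if m:
        px = float(m.group(1))
    m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', xml)
    if m and float(m.group(1)) > 0:
        fr = 1.0 / float(m.group(1))
    return px, fr


def write_movie(path: str | Path, movie: MovieStack) -> None:
    """Write a movie as OME-TIFF with pixel size and frame interval metadata."""
    tifffile.imwrite(
        Path(path),
        movie.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TYX",
            "PhysicalSizeX": movie.pixel_size_um,
            "PhysicalSizeY": movie.pixel_size_um,
            "TimeIncrement": 1.0 / movie.frame_rate_hz,
        },
    )


# ---------------------------------------------------------------------------
# timeline construction


def build_timeline(
    protocol: StimulationProtocol,
    movie_duration_s: float,
    nh4_delay_s: float | None = 50.0,
    nh4_duration_s: float = 10.0,
    bleach: tuple[float, float] | None = None,
) -> EpochTimeline:
    """Lay the stimulation paradigm, NH4+ dequench and optional bleach on the movie clock.

    ``nh4_delay_s`` is measured from the end of the last stimulation train
    (the assay dequenches 50 s or 80 s after the last train); ``None``
    omits the NH4 epoch.  ``bleach`` is an optional ``(t_start, t_end)``.
    """
    epochs: list[Epoch] = []
    if protocol.t_first_train_s > 0:
        epochs.append(Epoch("baseline", 0.0, protocol.t_first_train_s))
    trains = protocol.train_intervals()
    if trains[-1][1] > movie_duration_s:
        raise ValueError(
            f"protocol ends at {trains[-1][1]:.1f} s, beyond movie of {movie_duration_s:.1f} s"
        )
    for i, (t0, t1) in enumerate(trains):
        epochs.append(Epoch("stim_train", t0, t1))
        if i + 1 < len(trains):
            nxt = trains[i + 1][0]
            within_burst = (i + 1) % protocol.trains_per_burst != 0
            epochs.append(Epoch("inter_train" if within_burst else "inter_burst", t1, nxt))
    t_end_stim = trains[-1][1]
    if nh4_delay_s is not None:
        t_nh4 = t_end_stim + nh4_delay_s
        t_nh4_end = min(t_nh4 + nh4_duration_s, movie_duration_s)
        if t_nh4 >= movie_duration_s:
            raise ValueError("NH4 epoch starts beyond movie duration")
        if t_nh4 > t_end_stim:
            epochs.append(Epoch("post_stim", t_end_stim, t_nh4))
        epochs.append(Epoch("nh4", t_nh4, t_nh4_end))
    elif movie_duration_s > t_end_stim:
        epochs.append(Epoch("post_stim", t_end_stim, movie_duration_s))
    if bleach is not None:
        epochs.append(Epoch("bleach", bleach[0], bleach[1]))
    return EpochTimeline(tuple(epochs))


# ---------------------------------------------------------------------------
# tables and configs

ROI_COLUMNS = ["roi_id", "row", "col", "half_width_px"]


def write_roi_table(path: str | Path, rois: Iterable[RoiBox]) -> None:
    rows = [
        {"roi_id": r.roi_id, "row": r.center_rc[0], "col": r.center_rc[1],
         "half_width_px": r.half_width_px}
        for r in rois
    ]
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(Path(path), index=False)


def read_roi_table(path: str | Path, image_shape_rc: tuple[int, int] | None = None,
                   one_based: bool = False) -> list[RoiBox]:
    """Read an ROI table (CSV: roi_id, row, col, half_width_px).

    ``one_based=True`` shifts ImageJ-style 1-based coordinates to this
    package's 0-based convention.
    """
    df = pd.read_csv(Path(path))
    if df.empty:
        return []
    if df["roi_id"].duplicated().any():
        raise ValueError("duplicate roi_id in ROI table")
    shift = 1 if one_based else 0
    rois = [
        RoiBox((int(row.row) - shift, int(row.col) - shift),
               int(row.half_width_px), roi_id=int(row.roi_id))
        for row in df.itertuples()
    ]
    if image_shape_rc is not None:
        for r in rois:
            if not r.inside(image_shape_rc):
                raise ValueError(f"ROI {r.roi_id} box leaves image bounds {image_shape_rc}")
    return rois


def write_results(path: str | Path, table: pd.DataFrame,
                  require_keys: bool = True) -> None:
    """Write a result table; every row must carry the grouping keys the
    statistics stage needs (neuron_id, condition, experiment_id)."""
    if require_keys:
        missing = {"neuron_id", "condition", "experiment_id"} - set(table.columns)
        if missing:
            raise ValueError(f"result table missing grouping columns: {sorted(missing)}")
    path = Path(path)
    if path.suffix == ".json":
        table.to_json(path, orient="records", indent=1)
    else:
        table.to_csv(path, index=False)


def read_protocol(path: str | Path) -> StimulationProtocol:
    """Read a stimulation protocol from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return StimulationProtocol(**cfg)
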