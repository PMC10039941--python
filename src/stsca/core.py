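"""Shared domain types: electrode-array geometry, recordings, spike trains, lag axes.

Coordinate conventions
----------------------
Grid positions are 0-based ``(row, col)`` tuples.  Spatial lags are reported
as ``(xi, psi)`` where ``xi`` is the column lag and ``psi`` the row lag.  On
the ``(2W - 1) x (2W - 1)`` lag grid (``W = max(n_rows, n_cols)``) the zero
lag sits at 0-based index ``(W - 1, W - 1)``; for the default 10 x 10 array
this is the 1-based position (10, 10) of a 19 x 19 grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _signal

__all__ = [
    "ArrayGeometry",
    "Recording",
    "SpikeTrain",
    "LagAxes",
    "offset_count_table",
    "lag_of",
]


@dataclass(frozen=True, eq=False)
class ArrayGeometry:
    """A rectangular electrode grid with a present/absent mask.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; both must be >= 2.
    pitch_mm : float
        Center-to-center electrode spacing in mm (> 0).
    present : numpy.ndarray of bool, shape ``(n_rows, n_cols)``
        True where an electrode exists.
    channel_map : dict[int, tuple[int, int]]
        Bijection from channel id to its ``(row, col)`` position.  Must
        cover exactly the present positions.
    """

    n_rows: int
    n_cols: int
    pitch_mm: float
    present: np.ndarray
    channel_map: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if not self.pitch_mm > 0:
            raise ValueError("pitch_mm must be positive")
        present = np.asarray(self.present, dtype=bool)
        if present.shape != (self.n_rows, self.n_cols):
            raise ValueError("present mask shape does not match grid")
        object.__setattr__(self, "present", present)
        positions = {tuple(map(int, p)) for p in self.channel_map.values()}
        present_set = {tuple(map(int, rc)) for rc in zip(*np.nonzero(present))}
        if len(positions) != len(self.channel_map):
            raise ValueError("channel_map maps two channels to one position")
        if positions != present_set:
            raise ValueError("channel_map positions do not match present mask")
        object.__setattr__(
            self,
            "_pos_to_channel",
            {tuple(map(int, rc)): int(ch) for ch, rc in self.channel_map.items()},
        )

    # -- basic queries ---------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channel_map)

    @property
    def channel_ids(self) -> np.ndarray:
        return np.array(sorted(self.channel_map), dtype=np.int64)

    @property
    def grid_side(self) -> int:
        """W = max(n_rows, n_cols); the lag grid is (2W - 1) per side."""
        return max(self.n_rows, self.n_cols)

    def position(self, channel_id: int) -> tuple[int, int]:
        try:
            return self.channel_map[int(channel_id)]
        except KeyError:
            raise KeyError(f"unknown channel id {channel_id!r}") from None

    def channel_at(self, row: int, col: int) -> int:
        key = (int(row), int(col))
        if key not in self._pos_to_channel:  # type: ignore[attr-defined]
            raise KeyError(f"no electrode at position {key}")
        return self._pos_to_channel[key]  # type: ignore[attr-defined]

    def positions_for(self, channel_ids) -> np.ndarray:
        """Return an ``(n, 2)`` int array of (row, col) for the given ids."""
        return np.array([self.position(c) for c in channel_ids], dtype=np.int64)

    # -- constructors ----------------------------------------------------

    @classmethod
    def full_grid(cls, n_rows: int, n_cols: int, pitch_mm: float) -> "ArrayGeometry":
        present = np.ones((n_rows, n_cols), dtype=bool)
        cmap = {
            i: (int(r), int(c))
            for i, (r, c) in enumerate(np.argwhere(present))
        }
        return cls(n_rows, n_cols, pitch_mm, present, cmap)

    @classmethod
    def utah96(cls, pitch_mm: float = 0.4) -> "ArrayGeometry":
        """Default 10 x 10, 4 mm x 4 mm array with the four corners absent.

        96 channels numbered row-major over the present positions.
        """
        present = np.ones((10, 10), dtype=bool)
        for r, c in ((0, 0), (0, 9), (9, 0), (9, 9)):
            present[r, c] = False
        cmap = {
            i: (int(r), int(c))
            for i, (r, c) in enumerate(np.argwhere(present))
        }
        return cls(10, 10, pitch_mm, present, cmap)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        absent = [[int(r), int(c)] for r, c in np.argwhere(~self.present)]
        cmap = [[int(ch), int(r), int(c)] for ch, (r, c) in sorted(self.channel_map.items())]
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "n_cols": self.n_cols,
                "pitch_mm": self.pitch_mm,
                "absent_positions": absent,
                "channel_map": cmap,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArrayGeometry":
        d = json.loads(text)
        present = np.ones((d["n_rows"], d["n_cols"]), dtype=bool)
        for r, c in d["absent_positions"]:
            present[r, c] = False
        cmap = {int(ch): (int(r), int(c)) for ch, r, c in d["channel_map"]}
        return cls(d["n_rows"], d["n_cols"], float(d["pitch_mm"]), present, cmap)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ArrayGeometry":
        return cls.from_json(Path(path).read_text())


@dataclass(eq=False)
class Recording:
    """Uniformly sampled multichannel voltage data in microvolts.

    ``exclusion_mask`` is a validity mask (True = sample is valid); when
    None every sample is valid.
    """

    signals: np.ndarray
    fs_hz: float
    channel_ids: np.ndarray
    t0_s: float = 0.0
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
        if self.channel_ids.shape[0] != self.signals.shape[0]:
            raise ValueError("channel_ids length must match signal rows")
        if len(set(self.channel_ids.tolist())) != len(self.channel_ids):
            raise ValueError("duplicate channel ids")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != self.signals.shape:
                raise ValueError("exclusion_mask shape must match signals")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def valid_mask(self) -> np.ndarray:
        if self.exclusion_mask is None:
            return np.ones(self.signals.shape, dtype=bool)
        return self.exclusion_mask

    def channel_index(self, channel_ids) -> np.ndarray:
        """Row indices of the given channel ids within ``signals``."""
        lookup = {int(c): i for i, c in enumerate(self.channel_ids)}
        try:
            return np.array([lookup[int(c)] for c in channel_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"channel id {e.args[0]} not in recording") from None


@dataclass(eq=False)
class SpikeTrain:
    """Multi-unit threshold-crossing events as (channel id, sample index) pairs.

    Indices refer to a signal sampled at ``fs_hz``.  Within each channel the
    indices are strictly increasing.
    """

    channel_ids: np.ndarray
    sample_indices: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        if self.channel_ids.shape != self.sample_indices.shape or self.channel_ids.ndim != 1:
            raise ValueError("channel_ids and sample_indices must be 1-D and equal length")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        for ch in np.unique(self.channel_ids):
            idx = self.sample_indices[self.channel_ids == ch]
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"sample indices not strictly increasing on channel {ch}")

    def __len__(self) -> int:
        return int(self.channel_ids.shape[0])

    @property
    def times_s(self) -> np.ndarray:
        return self.sample_indices / self.fs_hz

    def chronological_order(self) -> np.ndarray:
        """Stable ordering by (time, channel); used for even/odd splitting."""
        return np.lexsort((self.channel_ids, self.sample_indices))

    def subset(self, index) -> "SpikeTrain":
        idx = np.asarray(index)
        order = np.lexsort((self.channel_ids[idx], self.sample_indices[idx]))
        return SpikeTrain(self.channel_ids[idx][order], self.sample_indices[idx][order], self.fs_hz)

    def for_channels(self, channels) -> "SpikeTrain":
        keep = np.isin(self.channel_ids, np.asarray(list(channels), dtype=np.int64))
        return SpikeTrain(self.channel_ids[keep], self.sample_indices[keep], self.fs_hz)

    def counts_per_channel(self) -> dict[int, int]:
        ch, n = np.unique(self.channel_ids, return_counts=True)
        return {int(c): int(k) for c, k in zip(ch, n)}


@dataclass(frozen=True, eq=False)
class LagAxes:
    """Lag axes of an st-SCA tensor.

    ``spatial_lags_px`` runs -(W-1)..(W-1); ``temporal_lags_samples`` runs
    -n..n at ``frame_fs_hz``.  The (0, 0, 0) lag is at 0-based tensor index
    ``(W - 1, W - 1, n)``.
    """

    spatial_lags_px: np.ndarray
    spatial_lags_mm: np.ndarray
    temporal_lags_samples: np.ndarray
    temporal_lags_s: np.ndarray

    @classmethod
    def build(cls, geometry: ArrayGeometry, n_lags: int, frame_fs_hz: float) -> "LagAxes":
        w = geometry.grid_side
        px = np.arange(-(w - 1), w, dtype=np.int64)
        ts = np.arange(-n_lags, n_lags + 1, dtype=np.int64)
        return cls(px, px * geometry.pitch_mm, ts, ts / frame_fs_hz)

    @property
    def origin_index(self) -> tuple[int, int, int]:
        w1 = (len(self.spatial_lags_px) - 1) // 2
        n = (len(self.temporal_lags_samples) - 1) // 2
        return (w1, w1, n)

    @property
    def max_lag_mm(self) -> float:
        return float(np.max(np.abs(self.spatial_lags_mm)))


def offset_count_table(geometry: ArrayGeometry) -> np.ndarray:
    """Per-lag pair-availability counts over the whole array.

    Entry at spatial lag ``(xi, psi)`` (index ``[psi + W - 1, xi + W - 1]``)
    is the number of present source positions ``p`` such that
    ``p + (psi, xi)`` is also present.  This is the spatial-count pattern
    accumulated by the spike-centered average when every channel fires once.
    """
    m = geometry.present.astype(np.float64)
    auto = _signal.correlate2d(m, m, mode="full")
    auto = np.rint(auto).astype(np.int64)
    w = geometry.grid_side
    out = np.zeros((2 * w - 1, 2 * w - 1), dtype=np.int64)
    r0 = (out.shape[0] - auto.shape[0]) // 2
    c0 = (out.shape[1] - auto.shape[1]) // 2
    out[r0 : r0 + auto.shape[0], c0 : c0 + auto.shape[1]] = auto
    return out


def lag_of(source_channel: int, target_position: tuple[int, int], geometry: ArrayGeometry) -> tuple[int, int]:
    """Spatial lag ``(xi, psi)`` = (column lag, row lag) from a source
    channel's position to a target ``(row, col)`` position."""
    r, c = geometry.position(source_channel)
    tr, tc = int(target_position[0]), int(target_position[1])
    if not (0 <= tr < geometry.n_rows and 0 <= tc < geometry.n_cols):
        raise ValueError(f"target position {target_position} outside grid")
    return (tc - c, tr - r)
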