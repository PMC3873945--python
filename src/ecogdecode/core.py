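"""Shared containers and error types for the ECoG decoding pipeline.

The pipeline's in-memory currency is small frozen-ish dataclasses wrapping
numpy arrays: an :class:`EcogRecording` (channels x samples surface
potentials), a :class:`Trajectory` (3 x samples hand position on the same
clock), an :class:`ElectrodeLayout` describing where each channel sits on
the rectangular grid relative to the central sulcus, and the
:class:`FeatureTensor` of normalized band-amplitude envelopes that the
decoder consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "InvalidArgumentError",
    "AlignmentError",
    "InsufficientDataError",
    "ConvergenceError",
    "ElectrodeLayout",
    "Band",
    "BandSet",
    "PHYSIOLOGICAL_BANDS",
    "fractionized_bands",
    "EcogRecording",
    "Trajectory",
    "FeatureTensor",
]


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class AlignmentError(ValueError):
    """Two time series that must share a clock do not."""


class InsufficientDataError(ValueError):
    """Not enough samples/rows remain to perform the operation."""


class ConvergenceError(RuntimeError):
    """Factor extraction could not proceed (degenerate residual)."""


# ---------------------------------------------------------------------------
# Electrode layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeLayout:
    """Rectangular electrode grid annotated relative to anatomy.

    Column 1 is the column nearest the central sulcus (CS); row 1 is the
    most medial row.  Rows/columns are 1-based.  Each channel id maps to
    exactly one (row, col) cell.
    """

    n_rows: int
    n_cols: int
    channel_ids: tuple[int, ...]
    positions: dict[int, tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid dimensions must be >= 1")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise InvalidArgumentError("duplicate channel ids")
        if set(self.positions) != set(self.channel_ids):
            raise InvalidArgumentError("positions must cover exactly the channel ids")
        seen: set[tuple[int, int]] = set()
        for ch, (r, c) in self.positions.items():
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise InvalidArgumentError(f"channel {ch} at ({r},{c}) outside grid")
            if (r, c) in seen:
                raise InvalidArgumentError(f"duplicate grid position ({r},{c})")
            seen.add((r, c))

    @classmethod
    def grid(
        cls,
        n_rows: int,
        n_cols: int,
        channel_ids: Sequence[int] | None = None,
    ) -> "ElectrodeLayout":
        """Full ``n_rows x n_cols`` grid.

        Default channel ids are 1..N assigned column-major: channels
        1..n_rows fill column 1 (nearest the CS) from row 1 (medial)
        outward, then column 2, and so on.
        """
        n = n_rows * n_cols
        if channel_ids is None:
            channel_ids = tuple(range(1, n + 1))
        else:
            channel_ids = tuple(int(c) for c in channel_ids)
            if len(channel_ids) != n:
                raise InvalidArgumentError("channel_ids length must equal n_rows*n_cols")
        positions = {}
        k = 0
        for col in range(1, n_cols + 1):
            for row in range(1, n_rows + 1):
                positions[channel_ids[k]] = (row, col)
                k += 1
        return cls(n_rows=n_rows, n_cols=n_cols, channel_ids=channel_ids, positions=positions)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def position_of(self, channel: int) -> tuple[int, int]:
        try:
            return self.positions[channel]
        except KeyError:
            raise InvalidArgumentError(f"unknown channel id {channel}") from None

    def channels_in_col(self, col: int) -> list[int]:
        return [ch for ch in self.channel_ids if self.positions[ch][1] == col]

    def channels_in_row(self, row: int) -> list[int]:
        return [ch for ch in self.channel_ids if self.positions[ch][0] == row]


# ---------------------------------------------------------------------------
# Frequency bands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidArgumentError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


@dataclass(frozen=True)
class BandSet:
    """Ordered, uniquely-named list of frequency bands."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("band names must be unique")
        if not self.bands:
            raise InvalidArgumentError("band set is empty")

    @classmethod
    def from_tuples(cls, triples: Iterable[tuple[str, float, float]]) -> "BandSet":
        return cls(tuple(Band(n, lo, hi) for n, lo, hi in triples))

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def index_of(self, name: str) -> int:
        for i, b in enumerate(self.bands):
            if b.name == name:
                return i
        raise InvalidArgumentError(f"unknown band {name!r}")


#: The nine motor-physiology bands used throughout: delta through high gamma.
PHYSIOLOGICAL_BANDS = BandSet.from_tuples(
    [
        ("delta", 1.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 14.0),
        ("beta1", 14.0, 20.0),
        ("beta2", 20.0, 30.0),
        ("gamma1", 30.0, 50.0),
        ("gamma2", 50.0, 90.0),
        ("gamma3", 90.0, 120.0),
        ("gamma4", 120.0, 150.0),
    ]
)


def fractionized_bands(width_hz: float = 10.0, max_hz: float = 150.0, min_hz: float = 0.5) -> BandSet:
    """Uniform ``width_hz``-wide bands covering (0, max_hz].

    The first band's low edge is floored at ``min_hz`` (a strictly-zero low
    edge is not band-pass-filterable), so the default yields 15 bands
    0.5-10, 10-20, ..., 140-150 Hz.
    """
    edges = np.arange(0.0, max_hz + 0.5 * width_hz, width_hz)
    triples = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo = max(lo, min_hz)
        triples.append((f"f{int(round(hi - width_hz))}_{int(round(hi))}", lo, hi))
    return BandSet.from_tuples(triples)


# ---------------------------------------------------------------------------
# Time-series containers
# ---------------------------------------------------------------------------


@dataclass
class EcogRecording:
    """Channels x samples surface-potential matrix with its grid layout."""

    data: np.ndarray
    fs: float
    layout: ElectrodeLayout

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("recording data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("recording contains non-finite values")
        if self.data.shape[0] != self.layout.n_channels:
            raise InvalidArgumentError(
                f"data has {self.data.shape[0]} rows but layout has "
                f"{self.layout.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EcogRecording":
        return EcogRecording(data=data, fs=self.fs, layout=self.layout)


@dataclass
class Trajectory:
    """3 x samples hand position (x, y, z) on the recording's clock."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise InvalidArgumentError("trajectory must be 3 x samples")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def speed(self) -> np.ndarray:
        """Instantaneous hand speed |dp/dt| (same length as the series)."""
        vel = np.gradient(self.data, axis=1) * self.fs
        return np.linalg.norm(vel, axis=0)


@dataclass
class FeatureTensor:
    """Normalized band-envelope features S_norm(channel, band, t).

    ``valid_from`` is the first sample index at which the causal
    normalization window is complete; values before it are zero-filled and
    must not enter fitting or evaluation.
    """

    values: np.ndarray  # (n_channels, n_bands, n_samples)
    fs: float
    band_set: BandSet
    valid_from: int
    channel_ids: tuple[int, ...]
    layout: ElectrodeLayout | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidArgumentError("feature tensor must be 3-D")
        if self.values.shape[1] != len(self.band_set):
            raise InvalidArgumentError("band axis does not match band set")
        if self.values.shape[0] != len(self.channel_ids):
            raise InvalidArgumentError("channel axis does not match channel ids")
        tail = self.values[:, :, self.valid_from :]
        if tail.size and not np.all(np.isfinite(tail)):
            raise InvalidArgumentError("non-finite feature values at/after valid_from")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]
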