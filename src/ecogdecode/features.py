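"""Lag-embedded design matrix and train/test splitting.

The decoder is the linear-in-history map

    p_hat(t) = a + sum_{i,j,k} w(i, j, k*dt) * S_norm(i, j, t - k*dt),

with k = 1..20 lags of dt = 30 ms — a 0.6-s strictly-causal history window.
This module flattens that summation structure into an explicit design
matrix whose columns carry a (channel, band, lag) bijection, so every
weight of the fitted model remains addressable, and implements the
contiguous-in-time train/test split (first ``train_s`` seconds for
fitting, the following ``test_s`` for evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FeatureTensor,
    InsufficientDataError,
    InvalidArgumentError,
    Trajectory,
)

__all__ = [
    "LagSpec",
    "DesignMatrix",
    "TargetMatrix",
    "lag_embed",
    "split_train_test",
    "restrict_channels",
    "restrict_bands",
]


@dataclass(frozen=True)
class LagSpec:
    """History window: ``n_lags`` steps of ``step_s`` strictly before t."""

    step_s: float = 0.03
    n_lags: int = 20

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise InvalidArgumentError("lag step must be positive")
        if self.n_lags < 1:
            raise InvalidArgumentError("need at least one lag")

    @property
    def span_s(self) -> float:
        return self.n_lags * self.step_s

    def step_samples(self, fs: float) -> int:
        step = self.step_s * fs
        if abs(step - round(step)) > 1e-6 or round(step) < 1:
            raise InvalidArgumentError(
                f"lag step {self.step_s}s is not a whole number of samples at {fs} Hz"
            )
        return int(round(step))


@dataclass
class DesignMatrix:
    """Rows = retained time points; columns indexed by (channel, band, lag).

    ``channel_of``/``band_of``/``lag_of`` are parallel per-column arrays
    realizing the column bijection; ``t_index`` holds each row's sample
    index on the original clock.
    """

    X: np.ndarray
    channel_of: np.ndarray  # channel id per column
    band_of: np.ndarray  # band name per column
    lag_of: np.ndarray  # lag index k (1-based) per column
    t_index: np.ndarray
    fs: float
    stride: int
    #: full channel/band universe of the originating embedding; restriction
    #: requests are validated against these, so restrictions compose as
    #: set intersection
    all_channels: tuple = ()
    all_bands: tuple = ()

    def __post_init__(self) -> None:
        ncols = self.X.shape[1]
        if not (len(self.channel_of) == len(self.band_of) == len(self.lag_of) == ncols):
            raise InvalidArgumentError("column metadata does not match design width")
        keys = list(zip(self.channel_of, self.band_of, self.lag_of))
        if len(set(keys)) != ncols:
            raise InvalidArgumentError("(channel, band, lag) keys are not unique")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def channels(self) -> list[int]:
        return list(dict.fromkeys(self.channel_of.tolist()))

    @property
    def bands(self) -> list[str]:
        return list(dict.fromkeys(self.band_of.tolist()))

    @property
    def times_s(self) -> np.ndarray:
        return self.t_index / self.fs

    def _subset(self, mask: np.ndarray) -> "DesignMatrix":
        if mask.all():
            return self  # identity restriction: keep the exact same arrays
        return DesignMatrix(
            X=self.X[:, mask],
            channel_of=self.channel_of[mask],
            band_of=self.band_of[mask],
            lag_of=self.lag_of[mask],
            t_index=self.t_index,
            fs=self.fs,
            stride=self.stride,
            all_channels=self.all_channels,
            all_bands=self.all_bands,
        )

    def row_slice(self, mask: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            X=self.X[mask],
            channel_of=self.channel_of,
            band_of=self.band_of,
            lag_of=self.lag_of,
            t_index=self.t_index[mask],
            fs=self.fs,
            stride=self.stride,
            all_channels=self.all_channels,
            all_bands=self.all_bands,
        )

    def reshape_coefficients(self, B: np.ndarray) -> tuple[np.ndarray, list[int], list[str], np.ndarray]:
        """View a (n_cols, n_out) coefficient matrix as w(i, j, k) per axis.

        Returns ``(W, channels, bands, lags)`` with ``W`` shaped
        (n_channels, n_bands, n_lags, n_out).
        """
        chans = self.channels
        bands = self.bands
        lags = np.unique(self.lag_of)
        n_out = B.shape[1]
        W = np.zeros((len(chans), len(bands), len(lags), n_out))
        ci = {c: i for i, c in enumerate(chans)}
        bi = {b: i for i, b in enumerate(bands)}
        li = {k: i for i, k in enumerate(lags.tolist())}
        for col in range(self.n_cols):
            W[ci[self.channel_of[col]], bi[self.band_of[col]], li[self.lag_of[col]]] = B[col]
        return W, chans, bands, lags


@dataclass
class TargetMatrix:
    """Samples x 3 hand positions aligned row-for-row with a design matrix."""

    Y: np.ndarray
    t_index: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.Y.shape[0]

    def row_slice(self, mask: np.ndarray) -> "TargetMatrix":
        return TargetMatrix(Y=self.Y[mask], t_index=self.t_index[mask])


def lag_embed(
    feat: FeatureTensor,
    traj: Trajectory,
    lags: LagSpec = LagSpec(),
    stride_s: float = 0.03,
) -> tuple[DesignMatrix, TargetMatrix]:
    """Build the design/target pair realizing the decoder's summation.

    Rows are placed on a ``stride_s`` grid; each row at time t stacks
    S_norm(i, j, t - k*dt) for k = 1..n_lags over all channels and bands
    (channel-major, then band, lag fastest), and pairs it with the hand
    position at t.  Rows whose history would touch samples before
    ``valid_from`` are dropped.
    """
    if feat.fs != traj.fs:
        raise InvalidArgumentError("feature tensor and trajectory must share a clock")
    if feat.n_samples != traj.n_samples:
        raise InvalidArgumentError("feature tensor and trajectory lengths differ")
    if stride_s < 1.0 / feat.fs:
        raise InvalidArgumentError("stride below one sample period")
    stride = int(round(stride_s * feat.fs))
    step = lags.step_samples(feat.fs)
    span = lags.n_lags * step

    t0 = feat.valid_from + span
    t0 = int(np.ceil(t0 / stride)) * stride  # snap onto the stride grid
    times = np.arange(t0, feat.n_samples, stride)
    if times.size == 0:
        raise InsufficientDataError("no rows remain after warm-up and lag span")

    offsets = step * np.arange(1, lags.n_lags + 1)
    # gather -> (n_ch, n_bands, n_rows, n_lags) -> (rows, ch, band, lag)
    gathered = feat.values[:, :, times[:, None] - offsets[None, :]]
    Xt = np.transpose(gathered, (2, 0, 1, 3))
    n_rows = times.size
    X = Xt.reshape(n_rows, -1)

    n_ch, n_bands = feat.n_channels, feat.n_bands
    channel_of = np.repeat(np.array(feat.channel_ids), n_bands * lags.n_lags)
    band_of = np.tile(np.repeat(np.array(feat.band_set.names), lags.n_lags), n_ch)
    lag_of = np.tile(np.arange(1, lags.n_lags + 1), n_ch * n_bands)

    design = DesignMatrix(
        X=X,
        channel_of=channel_of,
        band_of=band_of,
        lag_of=lag_of,
        t_index=times,
        fs=feat.fs,
        stride=stride,
        all_channels=tuple(feat.channel_ids),
        all_bands=tuple(feat.band_set.names),
    )
    targets = TargetMatrix(Y=traj.data[:, times].T, t_index=times)
    return design, targets


def split_train_test(
    X: DesignMatrix,
    Y: TargetMatrix,
    train_s: float = 500.0,
    test_s: float = 200.0,
) -> tuple[tuple[DesignMatrix, TargetMatrix], tuple[DesignMatrix, TargetMatrix]]:
    """Contiguous temporal split: first ``train_s`` seconds, next ``test_s``.

    No row is shared; evaluation data always lies strictly after training
    data, so overlapping lag windows cannot leak across the boundary in
    the anticausal direction.
    """
    if not np.array_equal(X.t_index, Y.t_index):
        raise InvalidArgumentError("design and targets are not row-aligned")
    total_s = (X.t_index[-1] + 1) / X.fs
    if total_s < train_s + test_s - 1e-9:
        raise InsufficientDataError(
            f"need {train_s + test_s:.1f}s of embedded rows, have {total_s:.1f}s"
        )
    t = X.times_s
    train_mask = t < train_s
    test_mask = (t >= train_s) & (t < train_s + test_s)
    if not train_mask.any() or not test_mask.any():
        raise InsufficientDataError("empty train or test segment")
    return (
        (X.row_slice(train_mask), Y.row_slice(train_mask)),
        (X.row_slice(test_mask), Y.row_slice(test_mask)),
    )


def restrict_channels(X: DesignMatrix, channels) -> DesignMatrix:
    """Keep only columns belonging to ``channels`` (original order kept).

    ``channels`` is validated against the embedding's full channel
    universe; on an already-restricted design the effective selection is
    the intersection, so restrictions compose as set intersection.
    """
    channels = set(channels)
    if not channels:
        raise InvalidArgumentError("empty channel set")
    universe = set(X.all_channels) or set(X.channels)
    unknown = channels - universe
    if unknown:
        raise InvalidArgumentError(f"unknown channels {sorted(unknown)}")
    mask = np.isin(X.channel_of, list(channels))
    if not mask.any():
        raise InvalidArgumentError("restriction removes every column")
    return X._subset(mask)


def restrict_bands(X: DesignMatrix, bands) -> DesignMatrix:
    """Keep only columns belonging to ``bands`` (original order kept)."""
    bands = set(bands)
    if not bands:
        raise InvalidArgumentError("empty band set")
    universe = set(X.all_bands) or set(X.bands)
    unknown = bands - universe
    if unknown:
        raise InvalidArgumentError(f"unknown bands {sorted(unknown)}")
    mask = np.isin(X.band_of, list(bands))
    if not mask.any():
        raise InvalidArgumentError("restriction removes every column")
    return X._subset(mask)
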