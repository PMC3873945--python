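"""Synthetic ECoG + hand-trajectory generator with planted coupling.

No public dataset exists for the monkey center-out/reach-and-pull sessions
this pipeline targets, so every downstream stage is exercised on surrogate
recordings with a *known* ground truth: a designated subset of channels
("informative" channels) whose band-amplitude envelopes are linearly
coupled, with a short conduction-like delay, to a kinematic drive derived
from a smooth pseudo-periodic 3-D reach trajectory.

Generative model, per channel ``i`` and band ``b``::

    signal_i(t) = sum_b carrier_ib(t) * env_ib(t) + sigma_n * white_i(t)
                  + sigma_cm * common(t)

    env_ib(t)   = max(1 + m * w_b * drive_i(t - lag) + (m / sqrt(snr)) * eta_ib(t),
                      floor)

where ``carrier_ib`` is unit-variance noise exactly band-limited to band
``b`` (constructed in the frequency domain), ``drive_i`` is a
channel-specific unit-norm mixture of the standardized x/y/z position and
speed (standardized to unit variance), ``eta_ib`` is smooth unit-variance
envelope noise, ``m`` is the modulation depth, ``w_b`` the planted band
weight (zero on non-informative channels), and ``snr`` the ratio of
coupled-envelope variance to envelope-noise variance.  ``common`` is a
single trace shared by all channels so that common-average referencing is
non-trivial to test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    AlignmentError,
    ElectrodeLayout,
    BandSet,
    EcogRecording,
    InvalidArgumentError,
    PHYSIOLOGICAL_BANDS,
    Trajectory,
)

__all__ = [
    "GroundTruth",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_trajectory",
    "generate_ecog",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]

_ENV_FLOOR = 0.05
_MAX_LAG_S = 0.6


@dataclass(frozen=True)
class GroundTruth:
    """Planted coupling structure of a synthetic dataset."""

    informative_channels: frozenset[int]
    band_weights: dict[str, float]
    coupling_lag_s: float = 0.09
    snr: float = 10.0

    def validate(self, layout: ElectrodeLayout, band_set: BandSet) -> None:
        if not self.informative_channels <= set(layout.channel_ids):
            raise InvalidArgumentError("informative channels not in layout")
        unknown = set(self.band_weights) - set(band_set.names)
        if unknown:
            raise InvalidArgumentError(f"band weights reference unknown bands {unknown}")
        if any(w < 0 for w in self.band_weights.values()):
            raise InvalidArgumentError("band weights must be nonnegative")
        if not (0.0 <= self.coupling_lag_s <= _MAX_LAG_S):
            raise InvalidArgumentError(
                f"coupling lag must be in [0, {_MAX_LAG_S}] s, got {self.coupling_lag_s}"
            )
        if self.snr <= 0:
            raise InvalidArgumentError("snr must be positive")

    @classmethod
    def null(cls) -> "GroundTruth":
        """No coupling anywhere (null / negative-control dataset)."""
        return cls(informative_channels=frozenset(), band_weights={})


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic session; defaults emulate the 32-channel monkey.

    A ~700-s continuous session at 500 Hz on a 4 x 8 grid, ~5-s reach
    cycles, 10 informative channels carrying high-gamma (and gamma2)
    coupling at a 90-ms lag.
    """

    duration_s: float = 700.0
    fs: float = 500.0
    n_rows: int = 4
    n_cols: int = 8
    cycle_period_s: float = 5.0
    jitter_sd: float = 0.1
    truth: GroundTruth | None = None  # None -> default planted truth
    band_set: BandSet = field(default_factory=lambda: PHYSIOLOGICAL_BANDS)
    noise_sd: float = 1.0
    common_mode_sd: float = 1.0
    modulation_depth: float = 0.4
    seed: int = 0

    def layout(self) -> ElectrodeLayout:
        return ElectrodeLayout.grid(self.n_rows, self.n_cols)

    def resolved_truth(self) -> GroundTruth:
        if self.truth is not None:
            return self.truth
        layout = self.layout()
        # default: 10 informative channels (or all, on small grids) spread
        # evenly over the grid, coupled through the wide gamma bands
        n = layout.n_channels
        k = min(10, n)
        idx = np.linspace(0, n - 1, k).round().astype(int)
        chans = frozenset(layout.channel_ids[i] for i in idx)
        return GroundTruth(
            informative_channels=chans,
            band_weights={"gamma2": 1.0, "gamma3": 1.0, "gamma4": 1.0},
        )


@dataclass
class SyntheticDataset:
    recording: EcogRecording
    trajectory: Trajectory
    truth: GroundTruth
    seed: int
    config: GeneratorConfig | None = None


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

#: Per-axis reach amplitudes (arbitrary length units); the reach target sits
#: at roughly (2, 1.5, 1) relative to the rest position at the origin.
_AMPLITUDE = np.array([2.0, 1.5, 1.0])


def generate_trajectory(
    duration_s: float,
    fs: float,
    cycle_period_s: float = 5.0,
    jitter_sd: float = 0.1,
    seed: int = 0,
) -> Trajectory:
    """Smooth pseudo-periodic reach-and-return trajectory.

    Each ~``cycle_period_s`` cycle is a smooth reach from the rest position
    toward a target and back (a ``sin^2`` bump per axis).  ``jitter_sd``
    scales *all* stochastic components: per-cycle period and amplitude
    jitter plus a small smoothed additive wander.  With ``jitter_sd = 0``
    the output is exactly periodic and fully deterministic.
    """
    if duration_s <= 0 or fs <= 0 or cycle_period_s <= 0:
        raise InvalidArgumentError("duration_s, fs and cycle_period_s must be positive")
    if jitter_sd < 0:
        raise InvalidArgumentError("jitter_sd must be >= 0")

    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    nominal = int(round(cycle_period_s * fs))

    pos = np.zeros((3, n))
    t0 = 0
    while t0 < n:
        if jitter_sd > 0:
            dur = int(round(nominal * (1.0 + jitter_sd * float(np.clip(rng.standard_normal(), -3, 3)))))
            dur = max(dur, nominal // 4, 2)
            amp_fac = np.clip(1.0 + jitter_sd * rng.standard_normal(3), 0.25, 1.75)
        else:
            dur = nominal
            amp_fac = np.ones(3)
        u = np.arange(min(dur, n - t0)) / dur
        bump = np.sin(np.pi * u) ** 2
        pos[:, t0 : t0 + len(u)] = (_AMPLITUDE * amp_fac)[:, None] * bump[None, :]
        t0 += dur

    if jitter_sd > 0:
        # slow additive wander, ~0.15-s correlation scale, small vs amplitude
        wander = gaussian_filter1d(rng.standard_normal((3, n)), sigma=0.15 * fs, axis=-1)
        sd = wander.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        pos += (0.1 * jitter_sd) * _AMPLITUDE[:, None] * wander / sd

    return Trajectory(data=pos, fs=fs)


# ---------------------------------------------------------------------------
# ECoG synthesis
# ---------------------------------------------------------------------------


def _bandlimited_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float, low: float, high: float) -> np.ndarray:
    """Unit-variance noise whose spectrum is exactly confined to [low, high)."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[:, ~((freqs >= low) & (freqs < high))] = 0.0
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def kinematic_drive(trajectory: Trajectory, mixing: np.ndarray) -> np.ndarray:
    """Channel drives: unit-norm mixtures of standardized position + speed.

    ``mixing`` is (n_channels, 4) over [x, y, z, speed]; each returned row
    is standardized to zero mean / unit variance.
    """
    feats = np.vstack(
        [
            _standardize(trajectory.data[0]),
            _standardize(trajectory.data[1]),
            _standardize(trajectory.data[2]),
            _standardize(trajectory.speed()),
        ]
    )
    norm = np.linalg.norm(mixing, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return _standardize((mixing / norm) @ feats)


def generate_ecog(
    trajectory: Trajectory,
    layout: ElectrodeLayout,
    truth: GroundTruth,
    fs: float,
    common_mode_sd: float = 1.0,
    seed: int = 0,
    band_set: BandSet = PHYSIOLOGICAL_BANDS,
    noise_sd: float = 1.0,
    modulation_depth: float = 0.4,
) -> EcogRecording:
    """Synthesize a multichannel surface-potential recording.

    See the module docstring for the generative model.  Deterministic for a
    fixed seed.
    """
    if fs != trajectory.fs:
        raise AlignmentError(f"trajectory fs {trajectory.fs} != requested fs {fs}")
    truth.validate(layout, band_set)
    if modulation_depth <= 0:
        raise InvalidArgumentError("modulation_depth must be positive")

    n = trajectory.n_samples
    n_ch = layout.n_channels
    rng = np.random.default_rng(seed)
    # fixed draw order -> the carrier/noise streams do not depend on truth
    mixing = rng.standard_normal((n_ch, 4))
    drives = kinematic_drive(trajectory, mixing)
    d = int(round(truth.coupling_lag_s * fs))
    if d > 0:
        lagged = np.empty_like(drives)
        lagged[:, d:] = drives[:, :-d]
        lagged[:, :d] = drives[:, :1]
    else:
        lagged = drives

    m = modulation_depth
    env_noise_amp = m / np.sqrt(truth.snr)
    chan_index = {ch: i for i, ch in enumerate(layout.channel_ids)}
    informative = np.zeros(n_ch, dtype=bool)
    for ch in truth.informative_channels:
        informative[chan_index[ch]] = True

    data = np.zeros((n_ch, n))
    for band in band_set:
        carrier = _bandlimited_noise(rng, n_ch, n, fs, band.low_hz, band.high_hz)
        eta = gaussian_filter1d(rng.standard_normal((n_ch, n)), sigma=0.1 * fs, axis=-1)
        eta = _standardize(eta)
        env = 1.0 + env_noise_amp * eta
        w = truth.band_weights.get(band.name, 0.0)
        if w > 0 and informative.any():
            env[informative] += m * w * lagged[informative]
        np.maximum(env, _ENV_FLOOR, out=env)
        data += carrier * env

    data += noise_sd * rng.standard_normal((n_ch, n))
    if common_mode_sd > 0:
        data += common_mode_sd * rng.standard_normal(n)[None, :]
    return EcogRecording(data=data, fs=fs, layout=layout)


def make_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Compose trajectory + ECoG generation under one root seed."""
    ss = np.random.SeedSequence(config.seed)
    traj_seed, ecog_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    traj = generate_trajectory(
        config.duration_s,
        config.fs,
        cycle_period_s=config.cycle_period_s,
        jitter_sd=config.jitter_sd,
        seed=traj_seed,
    )
    truth = config.resolved_truth()
    rec = generate_ecog(
        traj,
        config.layout(),
        truth,
        fs=config.fs,
        common_mode_sd=config.common_mode_sd,
        seed=ecog_seed,
        band_set=config.band_set,
        noise_sd=config.noise_sd,
        modulation_depth=config.modulation_depth,
    )
    return SyntheticDataset(recording=rec, trajectory=traj, truth=truth, seed=config.seed, config=config)


# ---------------------------------------------------------------------------
# On-disk container: HDF5 + JSON truth sidecar
# ---------------------------------------------------------------------------


def _truth_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth.json")


def save_dataset(dataset: SyntheticDataset, path: str | Path) -> Path:
    """Write recording/trajectory/layout to HDF5 plus a JSON truth sidecar.

    Float payloads round-trip losslessly (stored as float64).
    """
    path = Path(path)
    rec, layout = dataset.recording, dataset.recording.layout
    with h5py.File(path, "w") as f:
        f.create_dataset("ecog", data=rec.data)
        f.create_dataset("trajectory", data=dataset.trajectory.data)
        f.attrs["fs"] = rec.fs
        tab = np.array(
            [[ch, *layout.positions[ch]] for ch in layout.channel_ids], dtype=np.int64
        )
        f.create_dataset("layout", data=tab)  # columns: channel, row, col
        f.attrs["n_rows"] = layout.n_rows
        f.attrs["n_cols"] = layout.n_cols
    sidecar = {
        "seed": dataset.seed,
        "truth": {
            "informative_channels": sorted(dataset.truth.informative_channels),
            "band_weights": dataset.truth.band_weights,
            "coupling_lag_s": dataset.truth.coupling_lag_s,
            "snr": dataset.truth.snr,
        },
    }
    _truth_sidecar(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_dataset(path: str | Path) -> SyntheticDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        ecog = f["ecog"][()]
        traj = f["trajectory"][()]
        fs = float(f.attrs["fs"])
        tab = f["layout"][()]
        n_rows = int(f.attrs["n_rows"])
        n_cols = int(f.attrs["n_cols"])
    positions = {int(ch): (int(r), int(c)) for ch, r, c in tab}
    layout = ElectrodeLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        channel_ids=tuple(int(ch) for ch, _, _ in tab),
        positions=positions,
    )
    side = json.loads(_truth_sidecar(path).read_text())
    truth = GroundTruth(
        informative_channels=frozenset(side["truth"]["informative_channels"]),
        band_weights=dict(side["truth"]["band_weights"]),
        coupling_lag_s=float(side["truth"]["coupling_lag_s"]),
        snr=float(side["truth"]["snr"]),
    )
    return SyntheticDataset(
        recording=EcogRecording(data=ecog, fs=fs, layout=layout),
        trajectory=Trajectory(data=traj, fs=fs),
        truth=truth,
        seed=int(side["seed"]),
    )
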