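"""Pipeline configuration: one schema-checked object drives every stage.

A :class:`PipelineConfig` nests the generator settings, the decoding
settings (band set, lag window, stride, split, CV / latent-count policy)
and the electrode-selection settings, all under a single root seed, and
round-trips through plain dicts / YAML so that every report can echo the
exact configuration that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .core import BandSet, InvalidArgumentError, PHYSIOLOGICAL_BANDS, fractionized_bands
from .features import LagSpec
from .synthetic import GeneratorConfig, GroundTruth

__all__ = ["DecodingConfig", "SelectionConfig", "PipelineConfig", "resolve_band_set"]


def resolve_band_set(spec: Any) -> BandSet:
    """Band set from a name ('physiological' / 'fractionized') or triples."""
    if isinstance(spec, BandSet):
        return spec
    if spec in (None, "physiological"):
        return PHYSIOLOGICAL_BANDS
    if spec == "fractionized":
        return fractionized_bands()
    if isinstance(spec, (list, tuple)):
        return BandSet.from_tuples([(str(n), float(lo), float(hi)) for n, lo, hi in spec])
    raise InvalidArgumentError(f"cannot interpret band set spec {spec!r}")


@dataclass
class DecodingConfig:
    """Feature-to-prediction settings shared by every fit in a run."""

    band_set: BandSet = field(default_factory=lambda: PHYSIOLOGICAL_BANDS)
    lag: LagSpec = field(default_factory=LagSpec)
    stride_s: float = 0.03
    train_s: float = 500.0
    test_s: float = 200.0
    k_folds: int = 10
    max_latent: int = 20
    plateau_tol: float = 0.01
    latent_cap: int = 20
    #: "cv" selects the count once on the full model via blocked CV + PRESS;
    #: an integer pins it (e.g. 20, the original fixed choice).
    n_latent: int | str = "cv"
    #: training rows this close (in seconds) to a held-out CV block are
    #: dropped; None derives one feature horizon (normalization window +
    #: lag span + envelope smoothing) so fold scoring stays leakage-free
    cv_embargo_s: float | None = None

    def __post_init__(self) -> None:
        if self.stride_s <= 0 or self.train_s <= 0 or self.test_s <= 0:
            raise InvalidArgumentError("stride/train/test durations must be positive")
        if self.k_folds < 2 or self.max_latent < 1 or self.latent_cap < 1:
            raise InvalidArgumentError("bad CV / latent settings")
        if isinstance(self.n_latent, str) and self.n_latent != "cv":
            raise InvalidArgumentError("n_latent must be an integer or 'cv'")


@dataclass
class SelectionConfig:
    """Electrode-selection settings."""

    #: Location-based group sizes; None derives the grid's natural ladder
    #: (3, 6, 9, 12, then 15 or 16 depending on the array).
    sizes: tuple[int, ...] | None = None
    #: Within-column fill order for partial groups; informative electrodes
    #: cluster laterally, so the lateral end is filled first by default.
    fill_order: str = "lateral_first"
    #: Sizes for the performance-based R^2-vs-k curve; None means a dense
    #: low-k grid (1..12) then 16, 24, ... up to the full array.
    incremental_sizes: tuple[int, ...] | None = None

    def resolved_sizes(self, n_channels: int) -> tuple[int, ...]:
        if self.sizes is not None:
            return tuple(self.sizes)
        ladder = [s for s in (3, 6, 9, 12) if s < n_channels]
        top = 15 if n_channels == 15 else min(16, n_channels)
        if top not in ladder:
            ladder.append(top)
        return tuple(ladder)

    def resolved_incremental_sizes(self, n_channels: int) -> tuple[int, ...]:
        if self.incremental_sizes is not None:
            return tuple(self.incremental_sizes)
        ks = list(range(1, min(12, n_channels) + 1))
        ks += [k for k in (16, 24, 32) if 12 < k < n_channels]
        if n_channels not in ks:
            ks.append(n_channels)
        return tuple(ks)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    decode: DecodingConfig = field(default_factory=DecodingConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    load_path: str | None = None

    def __post_init__(self) -> None:
        # one root seed flows into the generator
        self.generator.seed = self.seed

    # -- dict / YAML round-trip -------------------------------------------

    def to_dict(self) -> dict:
        gen = self.generator
        truth = gen.truth
        d = {
            "seed": self.seed,
            "load_path": self.load_path,
            "generator": {
                "duration_s": gen.duration_s,
                "fs": gen.fs,
                "n_rows": gen.n_rows,
                "n_cols": gen.n_cols,
                "cycle_period_s": gen.cycle_period_s,
                "jitter_sd": gen.jitter_sd,
                "noise_sd": gen.noise_sd,
                "common_mode_sd": gen.common_mode_sd,
                "modulation_depth": gen.modulation_depth,
                "bands": [(b.name, b.low_hz, b.high_hz) for b in gen.band_set],
                "truth": None
                if truth is None
                else {
                    "informative_channels": sorted(truth.informative_channels),
                    "band_weights": dict(truth.band_weights),
                    "coupling_lag_s": truth.coupling_lag_s,
                    "snr": truth.snr,
                },
            },
            "decode": {
                "bands": [(b.name, b.low_hz, b.high_hz) for b in self.decode.band_set],
                "lag_step_s": self.decode.lag.step_s,
                "n_lags": self.decode.lag.n_lags,
                "stride_s": self.decode.stride_s,
                "train_s": self.decode.train_s,
                "test_s": self.decode.test_s,
                "k_folds": self.decode.k_folds,
                "max_latent": self.decode.max_latent,
                "plateau_tol": self.decode.plateau_tol,
                "latent_cap": self.decode.latent_cap,
                "n_latent": self.decode.n_latent,
                "cv_embargo_s": self.decode.cv_embargo_s,
            },
            "selection": asdict(self.selection),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        gen_d = dict(d.get("generator") or {})
        truth_d = gen_d.pop("truth", None)
        truth = None
        if truth_d:
            truth = GroundTruth(
                informative_channels=frozenset(truth_d.get("informative_channels", [])),
                band_weights=dict(truth_d.get("band_weights", {})),
                coupling_lag_s=float(truth_d.get("coupling_lag_s", 0.09)),
                snr=float(truth_d.get("snr", 10.0)),
            )
        band_spec = gen_d.pop("bands", None)
        known_gen = {
            k: gen_d[k]
            for k in (
                "duration_s", "fs", "n_rows", "n_cols", "cycle_period_s",
                "jitter_sd", "noise_sd", "common_mode_sd", "modulation_depth",
            )
            if k in gen_d
        }
        unknown = set(gen_d) - set(known_gen)
        if unknown:
            raise InvalidArgumentError(f"unknown generator keys {sorted(unknown)}")
        generator = GeneratorConfig(truth=truth, band_set=resolve_band_set(band_spec), **known_gen)

        dec_d = dict(d.get("decode") or {})
        decode = DecodingConfig(
            band_set=resolve_band_set(dec_d.pop("bands", None)),
            lag=LagSpec(
                step_s=float(dec_d.pop("lag_step_s", 0.03)),
                n_lags=int(dec_d.pop("n_lags", 20)),
            ),
            **dec_d,
        )
        sel_d = dict(d.get("selection") or {})
        for key in ("sizes", "incremental_sizes"):
            if sel_d.get(key) is not None:
                sel_d[key] = tuple(int(v) for v in sel_d[key])
        selection = SelectionConfig(**sel_d)
        return cls(
            generator=generator,
            decode=decode,
            selection=selection,
            seed=int(d.get("seed", 0)),
            load_path=d.get("load_path"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InvalidArgumentError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})
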