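"""Electrode selection: location-based groups and performance-based ranking.

Two procedures for shrinking the electrode set:

* *location-based* — whole grid columns taken in order of proximity to the
  central sulcus (column 1 first), truncated to the requested sizes; the
  groups are nested by construction;
* *performance-based* — every electrode is scored by decoding with that
  electrode alone, electrodes are ranked by mean held-out R^2, and models
  are refit on the top-k sets for increasing k.

Both procedures evaluate with the same preprocessing, lag embedding,
train/test split and latent-count policy as the full model, so the two
methods coincide exactly at the full electrode count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ElectrodeLayout, InvalidArgumentError
from .config import DecodingConfig
from .features import lag_embed, restrict_bands, restrict_channels, split_train_test
from .pls import PlsModel, cross_validate, fit_pls_upto, r_squared, select_n_latent
from .preprocess import compute_feature_tensor
from .synthetic import SyntheticDataset

__all__ = [
    "SelectionResult",
    "PreparedDecoding",
    "prepare_decoding",
    "fit_and_evaluate",
    "location_groups",
    "column_groups",
    "row_groups",
    "single_channel_scores",
    "incremental_performance",
    "evaluate_groups",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Shared fit/evaluate machinery
# ---------------------------------------------------------------------------


@dataclass
class PreparedDecoding:
    """Embedded + split data with the resolved latent count; computed once
    per dataset/config pair and reused by every restricted fit."""

    train_X: object
    train_Y: object
    test_X: object
    test_Y: object
    layout: ElectrodeLayout
    n_latent: int
    cv_curve: object | None = None


def prepare_decoding(dataset: SyntheticDataset, config: DecodingConfig) -> PreparedDecoding:
    """Preprocess, embed, split, and resolve the latent-count policy.

    With ``n_latent='cv'`` the count is selected once on the *full* model
    (blocked 10-fold CV, PRESS plateau rule) and reused for every
    restricted fit, mirroring how the original analysis fixed the count
    after a single full-model CV.
    """
    feat = compute_feature_tensor(dataset.recording, bands=config.band_set)
    design, targets = lag_embed(feat, dataset.trajectory, lags=config.lag, stride_s=config.stride_s)
    (train_X, train_Y), (test_X, test_Y) = split_train_test(
        design, targets, train_s=config.train_s, test_s=config.test_s
    )
    curve = None
    if config.n_latent == "cv":
        max_latent = min(config.max_latent, train_X.n_rows - 1, train_X.n_cols)
        embargo_s = config.cv_embargo_s
        if embargo_s is None:
            # one feature horizon: normalization window + lag span + smoothing
            embargo_s = 2.0 + config.lag.span_s + 0.1
        embargo_rows = int(np.ceil(embargo_s / config.stride_s))
        curve = cross_validate(
            train_X.X, train_Y.Y, max_latent=max_latent,
            k_folds=config.k_folds, embargo_rows=embargo_rows,
        )
        n_latent = select_n_latent(curve, plateau_tol=config.plateau_tol, cap=config.latent_cap)
        logger.info("CV selected %d latent variables", n_latent)
    else:
        n_latent = int(config.n_latent)
    return PreparedDecoding(
        train_X=train_X, train_Y=train_Y, test_X=test_X, test_Y=test_Y,
        layout=dataset.recording.layout, n_latent=n_latent, cv_curve=curve,
    )


def fit_and_evaluate(
    prepared: PreparedDecoding,
    channels=None,
    bands=None,
) -> tuple[np.ndarray, float, PlsModel]:
    """Fit on the training split (optionally restricted) and score the
    held-out split; returns (per-axis R^2, mean R^2, model)."""
    tr, te = prepared.train_X, prepared.test_X
    if channels is not None:
        tr, te = restrict_channels(tr, channels), restrict_channels(te, channels)
    if bands is not None:
        tr, te = restrict_bands(tr, bands), restrict_bands(te, bands)
    model = fit_pls_upto(tr.X, prepared.train_Y.Y, prepared.n_latent)
    per_axis, mean = r_squared(prepared.test_Y.Y, model.predict(te.X))
    return per_axis, mean, model


def _scores_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["size", "r2_x", "r2_y", "r2_z", "r2_mean"])


@dataclass
class SelectionResult:
    """Ordered channel groups with per-group held-out R^2.

    For the two selection methods ("location", "performance") the group
    sequence is a nested chain and this is enforced; "partition" results
    (column/row groups) hold disjoint sets instead.
    """

    method: str  # "location", "performance" or "partition"
    groups: list[list[int]]
    scores: pd.DataFrame  # columns: size, r2_x, r2_y, r2_z, r2_mean
    ranking: pd.DataFrame | None = None  # per-channel table (performance method)
    best_size: int | None = None

    def __post_init__(self) -> None:
        if self.method in ("location", "performance"):
            for small, big in zip(self.groups, self.groups[1:]):
                if not set(small) <= set(big):
                    raise InvalidArgumentError("selection groups must be nested")


# ---------------------------------------------------------------------------
# Location-based selection
# ---------------------------------------------------------------------------


def _fill_order(layout: ElectrodeLayout, fill_order: str = "lateral_first") -> list[int]:
    """Channel order: column 1 (nearest CS) outward; within a column the
    lateral (high-row) end first by default."""
    if fill_order not in ("lateral_first", "medial_first"):
        raise InvalidArgumentError(f"unknown fill order {fill_order!r}")
    reverse = fill_order == "lateral_first"
    order: list[int] = []
    for col in range(1, layout.n_cols + 1):
        chans = layout.channels_in_col(col)
        chans.sort(key=lambda ch: layout.positions[ch][0], reverse=reverse)
        order.extend(chans)
    return order


def location_groups(
    layout: ElectrodeLayout,
    sizes,
    fill_order: str = "lateral_first",
) -> list[list[int]]:
    """Nested electrode groups expanding away from the central sulcus."""
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes) or sizes != sorted(sizes):
        raise InvalidArgumentError("sizes must be ascending positive counts")
    if sizes and sizes[-1] > layout.n_channels:
        raise InvalidArgumentError(
            f"requested {sizes[-1]} electrodes, grid has {layout.n_channels}"
        )
    order = _fill_order(layout, fill_order)
    return [order[:s] for s in sizes]


def column_groups(layout: ElectrodeLayout) -> dict[int, list[int]]:
    """Partition by grid column, keyed 1 (nearest CS) outward."""
    return {col: layout.channels_in_col(col) for col in range(1, layout.n_cols + 1)}


def row_groups(layout: ElectrodeLayout) -> dict[int, list[int]]:
    """Partition by grid row, keyed 1 (most medial) outward."""
    return {row: layout.channels_in_row(row) for row in range(1, layout.n_rows + 1)}


def evaluate_groups(
    groups,
    dataset: SyntheticDataset,
    config: DecodingConfig,
    prepared: PreparedDecoding | None = None,
    method: str = "location",
) -> SelectionResult:
    """Fit and score the pipeline for each channel group."""
    if prepared is None:
        prepared = prepare_decoding(dataset, config)
    groups = [list(g) for g in groups]
    rows = []
    for g in groups:
        if not g:
            raise InvalidArgumentError("empty channel group")
        per_axis, mean, _ = fit_and_evaluate(prepared, channels=g)
        rows.append(
            {"size": len(g), "r2_x": per_axis[0], "r2_y": per_axis[1], "r2_z": per_axis[2], "r2_mean": mean}
        )
    scores = _scores_frame(rows)
    best = int(scores.loc[scores["r2_mean"].idxmax(), "size"])
    return SelectionResult(method=method, groups=groups, scores=scores, best_size=best)


# ---------------------------------------------------------------------------
# Performance-based selection
# ---------------------------------------------------------------------------


def single_channel_scores(
    dataset: SyntheticDataset,
    config: DecodingConfig,
    bands=None,
    prepared: PreparedDecoding | None = None,
) -> pd.DataFrame:
    """Held-out mean R^2 of a decoder using each electrode alone.

    Optionally restricted to a band subset (e.g. just gamma3).  Sorted by
    descending mean R^2, ties broken by ascending channel id.
    """
    if prepared is None:
        prepared = prepare_decoding(dataset, config)
    rows = []
    for ch in prepared.layout.channel_ids:
        per_axis, mean, _ = fit_and_evaluate(prepared, channels=[ch], bands=bands)
        rows.append(
            {"channel": ch, "r2_x": per_axis[0], "r2_y": per_axis[1], "r2_z": per_axis[2], "r2_mean": mean}
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["r2_mean", "channel"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def incremental_performance(
    ranking: pd.DataFrame,
    dataset: SyntheticDataset,
    config: DecodingConfig,
    sizes,
    prepared: PreparedDecoding | None = None,
) -> SelectionResult:
    """Refit with the top-k ranked electrodes for each k in ``sizes``."""
    if prepared is None:
        prepared = prepare_decoding(dataset, config)
    ranked = [int(c) for c in ranking["channel"]]
    if set(ranked) != set(prepared.layout.channel_ids):
        raise InvalidArgumentError("ranking must cover every layout channel exactly once")
    sizes = sorted({int(s) for s in sizes})
    if sizes[0] < 1 or sizes[-1] > len(ranked):
        raise InvalidArgumentError("sizes out of range")
    groups = [ranked[:k] for k in sizes]
    result = evaluate_groups(groups, dataset, config, prepared=prepared, method="performance")
    result.ranking = ranking.reset_index(drop=True)
    return result
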