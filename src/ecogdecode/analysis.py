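"""Frequency-band contribution analysis and the end-to-end experiment driver.

The fitted decoder's weight tensor w(i, j, dt) is summarized per output
axis p as the percentage contribution of each band j,

    Con_fb(p, j) = 100 * sum_{i, dt} |w_p(i, j, dt)| / sum_{i, j, dt} |w_p(i, j, dt)|,

and bands are additionally scored by decoding with each band alone.
:func:`run_full_analysis` orchestrates the whole experiment — simulate (or
load) -> preprocess -> embed -> CV + fit -> both electrode selections ->
contributions -> per-band table — into one reproducible, serializable
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BandSet, ElectrodeLayout, InvalidArgumentError
from .config import DecodingConfig, PipelineConfig
from .features import DesignMatrix
from .pls import PlsModel
from .selection import (
    PreparedDecoding,
    SelectionResult,
    evaluate_groups,
    fit_and_evaluate,
    incremental_performance,
    location_groups,
    prepare_decoding,
    single_channel_scores,
)
from .synthetic import SyntheticDataset, load_dataset, make_dataset

__all__ = [
    "ContributionTable",
    "AnalysisReport",
    "band_contribution",
    "per_band_decoding",
    "performance_heatmap",
    "heatmap_to_scores",
    "compare_band_sets",
    "run_full_analysis",
    "save_report",
]

logger = logging.getLogger(__name__)

_AXES = ("x", "y", "z")


def band_contribution(model: PlsModel, design: DesignMatrix) -> pd.DataFrame:
    """Percent contribution of each band to each output axis.

    Index = band names (design order); columns = x, y, z, mean.  Each axis
    column sums to 100.  Raises for an all-zero weight tensor.
    """
    W, _, bands, _ = design.reshape_coefficients(model.B)  # (ch, band, lag, axes)
    absw = np.abs(W).sum(axis=(0, 2))  # (band, axes)
    totals = absw.sum(axis=0)
    if np.any(totals <= 0):
        raise InvalidArgumentError("all-zero weights: contribution undefined")
    con = 100.0 * absw / totals
    table = pd.DataFrame(con, index=bands, columns=list(_AXES))
    table["mean"] = table[list(_AXES)].mean(axis=1)
    return table


def per_band_decoding(
    dataset: SyntheticDataset,
    config: DecodingConfig,
    prepared: PreparedDecoding | None = None,
) -> pd.DataFrame:
    """Held-out R^2 decoding with each band alone (common split/model policy)."""
    if prepared is None:
        prepared = prepare_decoding(dataset, config)
    rows = []
    for band in config.band_set.names:
        per_axis, mean, _ = fit_and_evaluate(prepared, bands=[band])
        rows.append({"band": band, "r2_x": per_axis[0], "r2_y": per_axis[1],
                     "r2_z": per_axis[2], "r2_mean": mean})
    return pd.DataFrame(rows).set_index("band")


def performance_heatmap(scores: pd.DataFrame, layout: ElectrodeLayout) -> np.ndarray:
    """Grid matrix of per-channel scores; rows = grid rows (row 1 = medial),
    columns = grid columns (column 1 = central-sulcus side).  Cells without
    an electrode are NaN."""
    if set(scores["channel"]) != set(layout.channel_ids):
        raise InvalidArgumentError("score table does not cover the layout")
    mat = np.full((layout.n_rows, layout.n_cols), np.nan)
    for ch, val in zip(scores["channel"], scores["r2_mean"]):
        r, c = layout.position_of(int(ch))
        mat[r - 1, c - 1] = val
    return mat


def heatmap_to_scores(mat: np.ndarray, layout: ElectrodeLayout) -> pd.DataFrame:
    """Inverse of :func:`performance_heatmap` (round-trip helper)."""
    rows = []
    for ch in layout.channel_ids:
        r, c = layout.position_of(ch)
        rows.append({"channel": ch, "r2_mean": mat[r - 1, c - 1]})
    return pd.DataFrame(rows)


def compare_band_sets(
    dataset: SyntheticDataset,
    set_a: BandSet,
    set_b: BandSet,
    config: DecodingConfig,
) -> dict[str, float]:
    """Full fit/evaluation under two band sets on the common split."""
    out = {}
    for key, band_set in (("a", set_a), ("b", set_b)):
        cfg = DecodingConfig(
            band_set=band_set, lag=config.lag, stride_s=config.stride_s,
            train_s=config.train_s, test_s=config.test_s, k_folds=config.k_folds,
            max_latent=config.max_latent, plateau_tol=config.plateau_tol,
            latent_cap=config.latent_cap, n_latent=config.n_latent,
        )
        prepared = prepare_decoding(dataset, cfg)
        _, mean, _ = fit_and_evaluate(prepared)
        out[key] = mean
    return out


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Everything one experiment produced, reproducible from config + seed."""

    config: dict
    seed: int
    n_latent: int
    r2_global: dict  # {"x":, "y":, "z":, "mean":}
    cv_curve: dict | None  # {"n_components": [...], "press": [...], "r2": [...]}
    selection_location: SelectionResult
    selection_performance: SelectionResult
    column_table: pd.DataFrame
    row_table: pd.DataFrame
    contributions: pd.DataFrame
    per_band: pd.DataFrame
    single_channel: pd.DataFrame
    heatmap: np.ndarray
    truth: dict = field(default_factory=dict)

    def payload(self) -> dict:
        """Deterministic JSON-ready document (no timestamps)."""

        def sel(result: SelectionResult) -> dict:
            d = {
                "method": result.method,
                "groups": [list(map(int, g)) for g in result.groups],
                "scores": result.scores.to_dict(orient="records"),
                "best_size": result.best_size,
            }
            if result.ranking is not None:
                d["ranking"] = result.ranking.to_dict(orient="records")
            return d

        return {
            "config": self.config,
            "seed": self.seed,
            "truth": self.truth,
            "n_latent": self.n_latent,
            "r2_global": self.r2_global,
            "cv_curve": self.cv_curve,
            "selection_location": sel(self.selection_location),
            "selection_performance": sel(self.selection_performance),
            "column_table": self.column_table.reset_index().to_dict(orient="records"),
            "row_table": self.row_table.reset_index().to_dict(orient="records"),
            "contributions": self.contributions.reset_index(names="band").to_dict(orient="records"),
            "per_band": self.per_band.reset_index().to_dict(orient="records"),
            "single_channel": self.single_channel.to_dict(orient="records"),
            "heatmap": [[None if np.isnan(v) else v for v in row] for row in self.heatmap],
        }

    def to_json(self) -> str:
        return json.dumps(self.payload(), indent=2, sort_keys=True)


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Run the whole experiment under one config + seed."""
    if config.load_path:
        logger.info("loading dataset from %s", config.load_path)
        dataset = load_dataset(config.load_path)
    else:
        logger.info("simulating dataset (seed %d)", config.seed)
        dataset = make_dataset(config.generator)

    dec = config.decode
    prepared = prepare_decoding(dataset, dec)
    layout = prepared.layout

    per_axis, mean, model = fit_and_evaluate(prepared)
    r2_global = {a: float(v) for a, v in zip(_AXES, per_axis)} | {"mean": float(mean)}
    logger.info("global fit: mean R^2 = %.4f (n_latent=%d)", mean, prepared.n_latent)

    sizes = list(config.selection.resolved_sizes(layout.n_channels))
    if layout.n_channels not in sizes:
        sizes.append(layout.n_channels)
    loc_groups = location_groups(layout, sizes, fill_order=config.selection.fill_order)
    sel_loc = evaluate_groups(loc_groups, dataset, dec, prepared=prepared, method="location")

    ranking = single_channel_scores(dataset, dec, prepared=prepared)
    inc_sizes = config.selection.resolved_incremental_sizes(layout.n_channels)
    sel_perf = incremental_performance(ranking, dataset, dec, inc_sizes, prepared=prepared)

    def group_table(groups: dict[int, list[int]], label: str) -> pd.DataFrame:
        res = evaluate_groups(
            [groups[k] for k in sorted(groups)], dataset, dec, prepared=prepared, method="partition"
        )
        tab = res.scores.copy()
        tab.insert(0, label, sorted(groups))
        return tab.set_index(label)

    from .selection import column_groups, row_groups  # local: avoid cycle noise

    col_table = group_table(column_groups(layout), "col")
    row_table = group_table(row_groups(layout), "row")

    if model.n_latent > 0:
        contributions = band_contribution(model, prepared.train_X)
    else:
        # zero-latent (intercept-only) model: contributions undefined
        contributions = pd.DataFrame(
            np.nan, index=list(dec.band_set.names), columns=["x", "y", "z", "mean"]
        )
    per_band = per_band_decoding(dataset, dec, prepared=prepared)
    heatmap = performance_heatmap(ranking, layout)

    truth_d = {
        "informative_channels": sorted(dataset.truth.informative_channels),
        "band_weights": dict(dataset.truth.band_weights),
        "coupling_lag_s": dataset.truth.coupling_lag_s,
        "snr": dataset.truth.snr,
    }
    return AnalysisReport(
        config=config.to_dict(),
        seed=config.seed,
        n_latent=prepared.n_latent,
        r2_global=r2_global,
        cv_curve=None
        if prepared.cv_curve is None
        else {
            "n_components": prepared.cv_curve.n_components.tolist(),
            "press": prepared.cv_curve.press.tolist(),
            "r2": prepared.cv_curve.r2.tolist(),
            "baseline_press": float(prepared.cv_curve.baseline_press),
            "embargo_rows": prepared.cv_curve.embargo_rows,
        },
        selection_location=sel_loc,
        selection_performance=sel_perf,
        column_table=col_table,
        row_table=row_table,
        contributions=contributions,
        per_band=per_band,
        single_channel=ranking,
        heatmap=heatmap,
        truth=truth_d,
    )


def save_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """Write report.json plus flat CSV tables (atomic: temp then rename)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def atomic_write(path: Path, text: str) -> None:
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(text)
        tmp.replace(path)

    atomic_write(out_dir / "report.json", report.to_json())
    atomic_write(out_dir / "single_channel_scores.csv", report.single_channel.to_csv(index=False))
    atomic_write(out_dir / "per_band_r2.csv", report.per_band.to_csv())
    atomic_write(out_dir / "contributions.csv", report.contributions.to_csv())
    atomic_write(
        out_dir / "heatmap.csv",
        pd.DataFrame(report.heatmap).to_csv(index=False, header=False),
    )
    return out_dir / "report.json"
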