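"""End-to-end orchestration: archive -> indices -> phenophases -> forecast.

``run`` executes the configured stages and writes per-ROI index CSVs,
fit/date JSONs, a multi-ROI comparison matrix (ROI x index x {SOS, MOE, LOS,
EOS}), forecasts and metrics into the output directory.  ``compare_rois``
tabulates pairwise day differences between ROIs sharing an index — the
micro-environment contrast between canopy positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices as _indices
from . import lstm as _lstm
from . import metrics as _metrics
from . import roi as _roi
from . import synthetic as _synth
from .phenology import DoubleLogisticModel, DoubleLogisticParams, ExtractionError, FitError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One input source (image dir | series CSV | synthetic spec), plus stage
    options."""

    image_dir: str | None = None
    series_csv: str | None = None
    synthetic: dict | None = None
    roi_spec: str | None = None
    index_names: tuple = _indices.INDEX_NAMES
    hue_as_printed: bool = False
    smoothing_p: float | None = None
    forecast_index: str = "GEI"
    lstm: dict = field(default_factory=dict)
    horizon: int = 60
    run_forecast: bool = True
    out_dir: str = "canopyphen_out"
    seed: int = 0

    def __post_init__(self):
        sources = [s is not None for s in (self.image_dir, self.series_csv, self.synthetic)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source required "
                             "(image_dir | series_csv | synthetic)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def load_roi_specs(path) -> list[_roi.ROISpec]:
    """ROI specs from JSON/YAML: a list of {name, type: rect|polygon, coords}."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return [_roi.ROISpec(d["name"], d["type"],
                         tuple(tuple(c) if isinstance(c, (list, tuple)) else c
                               for c in d["coords"]))
            for d in data]


def _series_from_csv(path):
    df = pd.read_csv(path)
    out = []
    if "value" in df.columns:  # long format: roi, index, doy, value
        for (roi, idx), grp in df.groupby(["roi", "index"]):
            out.append(_indices.IndexSeries(roi, idx, grp["doy"].values,
                                            grp["value"].values))
    else:  # wide per-ROI format with one column per index
        idx_cols = [c for c in df.columns if c.upper() in _indices.INDEX_NAMES]
        for roi, grp in df.groupby("roi"):
            for c in idx_cols:
                out.append(_indices.IndexSeries(roi, c.upper(), grp["doy"].values,
                                                grp[c].values))
    if not out:
        raise ValueError(f"no index series found in {path}")
    return out


def _series_from_synthetic(spec: dict, index_names, seed: int):
    params = DoubleLogisticParams(**spec["params"])
    shifts = spec.get("roi_shifts_days", [0.0])
    noise = spec.get("noise_sd", 0.0)
    doy_start = spec.get("doy_start", 1)
    doy_end = spec.get("doy_end", 365)
    out = []
    for name in index_names:
        pairs = _synth.multi_roi_trajectories(
            params, shifts, doy_start=doy_start, doy_end=doy_end,
            noise_sd=noise, seed=seed, index_name=name)
        out.extend(series for _, series in pairs)
    return out


def fit_and_date(series, smoothing_p=None, random_state=0) -> dict:
    """Fit one series, extract dates; returns a JSON-ready record."""
    model = DoubleLogisticModel(smoothing_p=smoothing_p, random_state=random_state)
    model.fit(series.doys, series.values)
    rec = {
        "roi": series.roi,
        "index": series.index_name,
        "params": {k: getattr(model.params_, k)
                   for k in ("w_min", "w_max", "s", "a", "m_s", "m_a")},
        "diagnostics": {"rmse": model.diagnostics_.rmse,
                        "r2": model.diagnostics_.r_squared},
    }
    try:
        d = model.transition_dates()
        rec["dates"] = {"sos": d.sos, "moe": d.moe, "cos": d.cos, "eos": d.eos,
                        "los": d.los}
    except ExtractionError as exc:
        rec["dates"] = None
        rec["extraction_error"] = str(exc)
    return rec


def compare_rois(records) -> pd.DataFrame:
    """Pairwise per-index SOS/MOE/LOS/EOS differences (days) between ROIs."""
    rows = []
    by_index: dict[str, list] = {}
    for r in records:
        if r.get("dates"):
            by_index.setdefault(r["index"], []).append(r)
    for idx, recs in by_index.items():
        recs = sorted(recs, key=lambda r: r["roi"])
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                rows.append({
                    "index": idx, "roi_a": a["roi"], "roi_b": b["roi"],
                    **{f"d_{k}": a["dates"][k] - b["dates"][k]
                       for k in ("sos", "moe", "los", "eos")},
                })
    if not rows:
        logger.warning("fewer than two ROIs share an index; comparison table empty")
        return pd.DataFrame(columns=["index", "roi_a", "roi_b",
                                     "d_sos", "d_moe", "d_los", "d_eos"])
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report (also written to
    ``report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    # --- acquire index series ------------------------------------------------
    if config.image_dir is not None:
        if config.roi_spec:
            rois = load_roi_specs(config.roi_spec)
        else:
            manifest = Path(config.image_dir) / "manifest.json"
            if not manifest.exists():
                raise ValueError("image_dir input needs roi_spec or a manifest.json "
                                 "with ROI definitions")
            rois = [_roi.ROISpec(d["name"], d["type"], tuple(d["coords"]))
                    for d in json.loads(manifest.read_text())["rois"]]
        daily = _roi.extract_archive(config.image_dir, rois)
        series_list = []
        for name, recs in daily.items():
            _roi.daily_to_csv(recs, out / f"daily_rgb_{name}.csv")
            series_list.extend(_indices.compute_series(
                recs, config.index_names, config.hue_as_printed))
        report["stages"].append("extract")
    elif config.series_csv is not None:
        series_list = _series_from_csv(config.series_csv)
        report["stages"].append("load-series")
    else:
        series_list = _series_from_synthetic(config.synthetic, config.index_names,
                                             config.seed)
        report["stages"].append("simulate")
    _indices.series_to_csv(series_list, out / "index_series.csv")
    report["n_series"] = len(series_list)

    # --- phenophase fits -----------------------------------------------------
    records = []
    for s in series_list:
        try:
            records.append(fit_and_date(s, config.smoothing_p, config.seed))
        except (FitError, ValueError) as exc:
            logger.error("fit failed for %s/%s: %s", s.roi, s.index_name, exc)
            records.append({"roi": s.roi, "index": s.index_name, "error": str(exc)})
    (out / "phenophases.json").write_text(json.dumps(records, indent=1))
    matrix = pd.DataFrame([
        {"roi": r["roi"], "index": r["index"], **r["dates"]}
        for r in records if r.get("dates")])
    matrix.to_csv(out / "phenophase_matrix.csv", index=False)
    compare_rois(records).to_csv(out / "roi_comparison.csv", index=False)
    report["stages"].append("phenophase")
    report["n_dated"] = int(len(matrix))

    # --- forecast ------------------------------------------------------------
    if config.run_forecast:
        target = next((s for s in series_list
                       if s.index_name == config.forecast_index.upper()), None)
        if target is None:
            raise ValueError(f"forecast index {config.forecast_index!r} not among "
                             "computed series")
        lstm_cfg = dict(config.lstm)
        lstm_cfg.setdefault("seed", config.seed)
        model = _lstm.LSTMForecaster(**lstm_cfg).fit(target)
        n_test = model.split_[1] - model.split_[0]
        onestep = model.forecast(horizon=n_test, mode="one-step")
        rec = model.forecast(horizon=config.horizon, mode="recursive")
        m = _metrics.evaluate(onestep.y_true, onestep.y_pred)
        (out / "forecast_metrics.json").write_text(json.dumps({
            "mse": m.mse, "rmse": m.rmse, "mae": m.mae, "mape": m.mape,
            "bias": m.bias, "n": m.n}, indent=1))
        pd.concat([
            pd.DataFrame({"doy": onestep.doys, "y_true": onestep.y_true,
                          "y_pred": onestep.y_pred, "mode": "one-step"}),
            pd.DataFrame({"doy": rec.doys,
                          "y_true": rec.y_true if rec.y_true is not None else np.nan,
                          "y_pred": rec.y_pred, "mode": "recursive"}),
        ]).to_csv(out / "forecast.csv", index=False)
        res = _metrics.residuals(onestep.y_true, onestep.y_pred)
        theo, samp = _metrics.qq_points(res)
        pd.DataFrame({"doy": onestep.doys, "residual": res}).to_csv(
            out / "residuals.csv", index=False)
        pd.DataFrame({"theoretical": theo, "sample": samp}).to_csv(
            out / "qq.csv", index=False)
        report["stages"].append("forecast")
        report["forecast_metrics"] = {"mse": m.mse, "rmse": m.rmse,
                                      "mae": m.mae, "mape": m.mape}

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
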