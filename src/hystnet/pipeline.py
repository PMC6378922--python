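"""End-to-end orchestration of the neural and behavioral analyses.

The neural pipeline runs the full inference chain on synthetic (or
user-supplied) source data: ensemble normalization -> windowed MVAR
fits -> validation battery -> dDTF -> percentile thresholding ->
network metrics -> L3-vs-L1 condition contrast.  Windows failing
validation are excluded and counted.

The behavioral pipeline generates Low-High-Low event schedules, runs
the cognitive agent with and without declarative carryover, bins the
behavioral record, and reports the L1-vs-L3 mean reaction-time
difference with a seed-resampled interval (a descriptive contrast, not
an inferential test).

Every run can write its resolved configuration and seed next to its
outputs so results are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import actr, matb, metrics, mvar, synth, validation
from .connectivity import ConnectivityTensor, ddtf, threshold_edges
from .networks import Condition
from .timeseries import SourceTimeSeries, read_csv

__all__ = ["PipelineConfig", "run_neural_pipeline", "run_behavioral_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    fs: float = 128.0
    preset: str = "default"
    condition_minutes: float = 2.0
    n_trials: int = 8
    input_csv: str | None = None
    window_length_ms: float = 350.0
    window_step_samples: int = 30
    order: int = 16
    freq_range: tuple[float, float] = (2.0, 32.0)
    band: tuple[float, float] = (7.0, 30.0)
    threshold_percentile: float = 97.5
    stability_threshold: float = 0.0
    pc_threshold: float = 85.0
    alpha: float = 0.05
    fail_action: str = "warn"  # or "abort"
    agent_params: dict = field(default_factory=dict)
    n_behavioral_runs: int = 100
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["freq_range"] = list(self.freq_range)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("freq_range", "band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))


def run_neural_pipeline(config: PipelineConfig) -> dict:
    """Synthesize/load data, fit, validate, and measure connectivity.

    Returns a dict with per-condition validation summaries, connectivity
    tensors, network-metrics reports and the L3-vs-L1 contrast.
    """
    rng = np.random.default_rng(config.seed)
    if config.input_csv is not None:
        ts = read_csv(config.input_csv)
    else:
        ts = synth.make_session(
            preset=config.preset,
            condition_minutes=config.condition_minutes,
            fs=config.fs,
            n_trials=config.n_trials,
            seed=config.seed,
        )
    conds = ts.conditions() or ["all"]
    spec = mvar.WindowSpec(
        length_ms=config.window_length_ms,
        step_samples=config.window_step_samples,
        fs=ts.fs,
    )
    results: dict = {"conditions": {}, "config": config.to_dict()}
    reports: dict[str, metrics.NetworkMetricsReport] = {}
    tensors: dict[str, ConnectivityTensor] = {}
    for cond in conds:
        seg = ts.segment(cond) if cond != "all" else ts
        try:
            normed = mvar.ensemble_normalize(seg)
        except ValueError as err:
            raise RuntimeError(f"normalization failed for {cond}: {err}") from err
        # full battery at the epoch level (the unit the thresholds are
        # calibrated for); short windows are then screened for
        # stability and residual-ACF whiteness only.
        try:
            seg_model = mvar.fit_window(normed, p=config.order)
            seg_report = validation.validate_model(
                seg_model,
                normed.data,
                seed=int(rng.integers(0, 2**31 - 1)),
                alpha=config.alpha,
                pc_threshold=config.pc_threshold,
            )
        except Exception as err:
            raise RuntimeError(f"epoch validation failed for {cond}: {err}") from err
        epoch_ok = seg_report.stable and seg_report.consistent and seg_report.acf_white
        if config.fail_action == "abort" and not epoch_ok:
            raise RuntimeError(
                f"condition {cond} failed epoch-level validation: "
                f"{seg_report.to_dict()}"
            )
        try:
            models = mvar.sliding_fit(normed, spec, p=config.order)
        except Exception as err:
            raise RuntimeError(f"windowed fit failed for {cond}: {err}") from err
        w = spec.length_samples
        surviving = []
        n_unstable = 0
        n_nonwhite = 0
        for wi, model in enumerate(models):
            start = wi * spec.step_samples
            xw = normed.data[:, start : start + w, :]
            if validation.stability_index(model) >= config.stability_threshold:
                n_unstable += 1
                continue
            res = validation.residuals(model, xw)
            lags = max(2, min(12, res.shape[1] // 4 - 1))
            white, _ = validation.acf_whiteness(res, n_lags=lags, alpha=config.alpha)
            if not white:
                n_nonwhite += 1
                continue
            surviving.append(model)
        n_pass = len(surviving)
        if n_pass == 0:
            msg = f"no window of condition {cond} passed validation"
            if config.fail_action == "abort":
                raise RuntimeError(msg)
            results["conditions"][cond] = {
                "validation": {"n_windows": len(models), "n_passed": 0}
            }
            continue
        # time-varying tensor from the surviving short windows; network
        # summaries from the epoch-level model (the unit the published
        # per-condition metrics describe)
        tensor = ddtf(surviving, freq_range=config.freq_range)
        epoch_tensor = ddtf(seg_model, freq_range=config.freq_range)
        edges = threshold_edges(epoch_tensor, percentile=config.threshold_percentile)
        report = metrics.compute_report(epoch_tensor, band=config.band, condition=cond)
        tensors[cond] = tensor
        reports[cond] = report
        results["conditions"][cond] = {
            "validation": {
                "epoch": seg_report.to_dict(),
                "n_windows": len(models),
                "n_passed": n_pass,
                "n_unstable": n_unstable,
                "n_nonwhite": n_nonwhite,
                "pass_fraction": n_pass / len(models),
            },
            "thresholded_edges": {str(f): e for f, e in edges.items()},
            "metrics": report.to_dict(),
        }
    if {"L1", "L3"} <= set(reports):
        results["contrast"] = metrics.condition_contrast(reports)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.write(out / "config.yaml")
        _write_json(
            {k: v for k, v in results.items() if k != "config"},
            out / "neural_results.json",
        )
        for cond, tensor in tensors.items():
            tensor.to_csv(out / f"ddtf_{cond}.csv")
    results["_reports"] = reports
    results["_tensors"] = tensors
    return results


def run_behavioral_pipeline(config: PipelineConfig) -> dict:
    """Event schedules -> agent runs -> binned summaries -> L1/L3 contrast.

    The agent is run once per seed with declarative carryover on and
    off; the hysteresis contrast is the per-run difference in mean
    correct RT between the final and first low-demand blocks, summarized
    by a percentile interval across seeds.
    """
    params = actr.ActrParams(**config.agent_params) if config.agent_params else actr.ActrParams()
    master = np.random.default_rng(config.seed)
    deltas = {True: [], False: []}
    means = {True: {"L1": [], "L3": [], "H2": []}, False: {"L1": [], "L3": [], "H2": []}}
    first_records = {}
    first_bins = {}
    if config.condition_minutes <= 0:
        return {
            "bins": None,
            "contrast": {"n_runs": 0, "carryover": {}, "no_carryover": {}},
            "config": config.to_dict(),
        }
    for run in range(config.n_behavioral_runs):
        run_seed = int(master.integers(0, 2**31 - 1))
        sched = matb.make_lhl_schedule(config.condition_minutes, seed=run_seed)
        for carry in (True, False):
            p = dataclasses.replace(params, seed=run_seed)
            record = actr.run_session(sched, p, carryover=carry)
            resp = record.responses
            by_cond = resp[resp["correct"]].groupby("condition")["response_time_s"].mean()
            for cond in ("L1", "H2", "L3"):
                if cond in by_cond:
                    means[carry][cond].append(float(by_cond[cond]))
            if "L1" in by_cond and "L3" in by_cond:
                deltas[carry].append(float(by_cond["L3"] - by_cond["L1"]))
            if run == 0:
                first_records[carry] = record
                first_bins[carry] = actr.summarize_bins(record)

    def _interval(xs: list[float]) -> dict:
        if not xs:
            return {"mean": None, "lo": None, "hi": None, "n": 0}
        arr = np.asarray(xs)
        return {
            "mean": float(arr.mean()),
            "lo": float(np.percentile(arr, 2.5)),
            "hi": float(np.percentile(arr, 97.5)),
            "n": len(arr),
        }

    results = {
        "config": config.to_dict(),
        "contrast": {
            "carryover": _interval(deltas[True]),
            "no_carryover": _interval(deltas[False]),
            "mean_rt_by_condition": {
                "carryover": {c: float(np.mean(v)) if v else None for c, v in means[True].items()},
                "no_carryover": {
                    c: float(np.mean(v)) if v else None for c, v in means[False].items()
                },
            },
        },
        "bins": {
            "carryover": first_bins[True].to_dict(orient="records"),
            "no_carryover": first_bins[False].to_dict(orient="records"),
        },
        "_records": first_records,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.write(out / "config.yaml")
        _write_json(
            {k: v for k, v in results.items() if not k.startswith("_")},
            out / "behavioral_results.json",
        )
        for carry, record in first_records.items():
            tag = "carryover" if carry else "no_carryover"
            record.responses.to_csv(out / f"responses_{tag}.csv", index=False)
    return results
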