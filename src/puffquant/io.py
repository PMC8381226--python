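"""Trace files, run configuration and the end-to-end pipeline.

Traces are stored as two-column CSV (``time_s,value``, 17 significant
digits so write-read round trips are bit exact) with a JSON sidecar
``<name>.meta.json`` holding the sampling rate, recording mode, units
and protocol/condition metadata.  An optional single-file HDF5 mirror
stores the same fields.  :func:`run_pipeline` ties the stages together:
simulate a small population under a set of pharmacology conditions,
quantify every sweep, average per cell x condition, and run the
estimation and significance statistics, writing the result bundle
(measurements.csv, summaries.csv, effects.json, tests.json, trains.json
and a log) under one output directory, deterministically for a given
master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import effects as effects_mod
from . import infer as infer_mod
from . import quantify as quantify_mod
from . import synth, trains
from .quantify import QuantifyParams
from .trace import MODE_UNITS, CURRENT_CLAMP, PuffProtocol, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_trace_h5",
    "write_trace_h5",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("puffquant")

_TIME_JITTER_S = 1e-9


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace as CSV plus its JSON metadata sidecar."""
    path = Path(path)
    t = trace.times()
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{ti:.17g},{vi:.17g}\n")
    sidecar = path.with_suffix(".meta.json")
    meta = {
        "rate": trace.rate,
        "mode": trace.mode,
        "units": trace.units,
        "start_time": trace.start_time,
        "meta": trace.meta,
    }
    sidecar.write_text(json.dumps(meta, indent=1, default=_json_default))
    return path


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trace(path: str | Path) -> Trace:
    """Read a CSV trace written by :func:`write_trace`.

    Requires the exact ``time_s,value`` header, the ``.meta.json``
    sidecar, and uniform sampling (maximum timestamp jitter 1 ns).
    """
    path = Path(path)
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    info = json.loads(sidecar.read_text())
    with open(path) as fh:
        header = fh.readline().strip()
    if header != "time_s,value":
        raise ValueError(f"expected header 'time_s,value', got {header!r}")
    df = pd.read_csv(path, dtype=float, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    rate = float(info["rate"])
    start = float(info.get("start_time", t[0]))
    expected = start + np.arange(t.size) / rate
    jitter = np.max(np.abs(t - expected)) if t.size else 0.0
    if jitter > _TIME_JITTER_S:
        raise ValueError(
            f"non-uniform timestamps (max jitter {jitter:.3g} s > 1 ns)"
        )
    mode = info["mode"]
    if info.get("units") and info["units"] != MODE_UNITS.get(mode):
        raise ValueError(
            f"units {info['units']!r} inconsistent with mode {mode!r}"
        )
    return Trace(
        samples=df["value"].to_numpy(),
        rate=rate,
        mode=mode,
        start_time=start,
        meta=dict(info.get("meta", {})),
    )


def write_trace_h5(trace: Trace, path: str | Path) -> Path:
    """Single-file HDF5 mirror of the CSV + sidecar representation."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=trace.samples)
        ds.attrs["rate"] = trace.rate
        ds.attrs["mode"] = trace.mode
        ds.attrs["units"] = trace.units
        ds.attrs["start_time"] = trace.start_time
        ds.attrs["meta_json"] = json.dumps(trace.meta, default=_json_default)
    return path


def read_trace_h5(path: str | Path) -> Trace:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["samples"]
        return Trace(
            samples=ds[()],
            rate=float(ds.attrs["rate"]),
            mode=str(ds.attrs["mode"]),
            start_time=float(ds.attrs["start_time"]),
            meta=json.loads(ds.attrs["meta_json"]),
        )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, serializable to YAML.

    Every stochastic stage receives its own seed derived from ``seed``
    (via :class:`numpy.random.SeedSequence`), so one master seed fixes
    the whole result bundle.
    """

    seed: int = 0
    rate: float = 25_000.0
    mode: str = CURRENT_CLAMP
    n_cells: int = 6
    conditions: tuple[str, ...] = ("control", "Mec", "Mec+MLA")
    n_puffs: int = 5
    noise_sd: float | None = None  # None -> mode-appropriate default
    concentration: float = 1000.0
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    n_boot: int = 10_000
    n_mc: int = 10_000
    level: float = 0.95
    train_conditions: tuple[tuple[float, float], ...] = ()
    train_n_cells: int = 3

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_mc < 1:
            raise ValueError("n_boot and n_mc must be positive")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if len(self.conditions) < 2 or "control" not in self.conditions:
            raise ValueError("conditions must include 'control' plus treatments")
        for name in self.conditions:
            if name not in synth.SCENARIOS:
                raise ValueError(f"unknown scenario {name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["train_conditions"] = [list(t) for t in self.train_conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "quantify" in d and isinstance(d["quantify"], dict):
            d["quantify"] = QuantifyParams(**d["quantify"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "train_conditions" in d:
            d["train_conditions"] = tuple(
                (float(c), float(f)) for c, f in d["train_conditions"]
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-stage seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def simulate_experiment(
    config: RunConfig,
) -> list[tuple[str, int, Trace]]:
    """Per-cell, per-condition, per-puff sweeps for the config's design.

    Returns (cell_id, puff_index, trace) triples; each puff is its own
    sweep (puffs are a minute apart in the emulated protocol, so sweeps
    are independent apart from the cell's parameters).
    """
    neurons = synth.sample_population(
        n=config.n_cells, seed=int(_child_seeds(config.seed, 1)[0])
    )
    noise = config.noise_sd
    if noise is None:
        noise = (
            synth.DEFAULT_CC_NOISE_MV
            if config.mode == CURRENT_CLAMP
            else synth.DEFAULT_VC_NOISE_PA
        )
    n_sweeps = config.n_cells * len(config.conditions) * config.n_puffs
    seeds = _child_seeds(config.seed + 1, n_sweeps)
    out = []
    i = 0
    protocol = PuffProtocol.single_puff(concentration=config.concentration)
    for neuron in neurons:
        for condition in config.conditions:
            for puff in range(1, config.n_puffs + 1):
                sweep_seed = int(seeds[i])
                i += 1
                if config.mode == CURRENT_CLAMP:
                    rec = synth.synthesize_cc_recording(
                        membrane=neuron.membrane,
                        components=neuron.components,
                        protocol=protocol,
                        scenario=condition,
                        noise_sd=noise,
                        seed=sweep_seed,
                        rate=config.rate,
                    )
                    tr = rec.trace
                else:
                    tr = synth.synthesize_vc_recording(
                        components=neuron.components,
                        protocol=protocol,
                        scenario=condition,
                        noise_sd=noise,
                        seed=sweep_seed,
                        rate=config.rate,
                    )
                tr.meta.update(
                    cell_id=neuron.cell_id, condition=condition, puff_index=puff
                )
                out.append((neuron.cell_id, puff, tr))
    return out


def quantify_sweeps(
    sweeps: list[tuple[str, int, Trace]],
    params: QuantifyParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every sweep and average per cell x condition.

    Returns (measurements, summaries) DataFrames matching the CSV
    outputs of the pipeline.
    """
    measurements = []
    for _cell, puff_idx, tr in sweeps:
        onset = float(tr.meta["puff_times"][0])
        m = quantify_mod.quantify_sweep(tr, onset, puff_index=puff_idx, params=params)
        measurements.append(dataclasses.asdict(m))
    mdf = pd.DataFrame(measurements)
    summaries = []
    for (cell, cond), grp in mdf.groupby(["cell_id", "condition"], sort=False):
        summaries.append(
            {
                "cell_id": cell,
                "condition": cond,
                "mean_spike_count": grp["spike_count"].mean(),
                "mean_area": grp["area"].mean(),
                "n_puffs": len(grp),
            }
        )
    return mdf, pd.DataFrame(summaries)


def _effects_json(summary: dict, n_boot: int, level: float) -> dict:
    out = {"layout": summary["layout"], "effects": []}
    for eff in summary["effects"]:
        x, dens = summary["densities"][eff.treatment]
        out["effects"].append(
            {
                "treatment": eff.treatment,
                "control": eff.control,
                "control_mean": eff.control_mean,
                "treatment_mean": eff.treatment_mean,
                "mean_difference": eff.mean_difference,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "level": level,
                "n_boot": n_boot,
                "seed": eff.seed,
                "z0": eff.z0,
                "acceleration": eff.acceleration,
                "n_cells": eff.n_cells,
                "degenerate": eff.degenerate,
                "density_x": [round(float(v), 10) for v in x],
                "density_y": [round(float(v), 10) for v in dens],
            }
        )
    return out


def run_trains_stage(config: RunConfig, out_dir: Path) -> dict:
    """Simulate, quantify and analyse puff-train conditions."""
    results: dict[str, Any] = {}
    rows = []
    seeds = _child_seeds(
        config.seed + 2,
        max(1, config.train_n_cells * len(config.train_conditions) * 5),
    )
    i = 0
    noise = config.noise_sd
    if noise is None:
        noise = synth.DEFAULT_CC_NOISE_MV
    for conc, freq in config.train_conditions:
        profile = synth.DEFAULT_PROFILES[(conc, freq)]
        for cell in range(config.train_n_cells):
            for n_puffs in synth.TRAIN_PUFF_COUNTS:
                train = PuffProtocol.train(
                    n_puffs=n_puffs, frequency=freq, concentration=conc
                )
                rec = synth.simulate_train_response(
                    train=train,
                    profile=profile,
                    seed=int(seeds[i % seeds.size]),
                    noise_sd=noise,
                    rate=config.rate,
                )
                i += 1
                onset = float(train.puff_times[0])
                filtered = quantify_mod.median_filter_envelope(
                    rec.trace, config.quantify.median_window_ms
                )
                baseline = quantify_mod.estimate_baseline(
                    filtered,
                    onset,
                    config.quantify.baseline_window_s,
                    config.quantify.baseline_gap_s,
                )
                window = rec.trace.duration - onset - 2.0 / rec.trace.rate
                rows.append(
                    {
                        "cell_id": f"cell{cell:03d}",
                        "puff_count": n_puffs,
                        "frequency": freq,
                        "concentration": conc,
                        "mean_area": quantify_mod.response_area(
                            filtered, baseline, onset, window
                        ),
                        "mean_spike_count": quantify_mod.detect_spikes(
                            rec.trace, config.quantify.spike_threshold
                        ).count,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        table.to_csv(out_dir / "train_summaries.csv", index=False)
    for (conc, freq), grp in table.groupby(["concentration", "frequency"]):
        res = trains.analyze_trains(grp)
        results[f"{conc:g}uM_{freq:g}Hz"] = {
            "slope": res["fit"].slope,
            "intercept": res["fit"].intercept,
            "pearson_r": res["fit"].pearson_r,
            "ratio_10_1": res["ratio_10_1"],
            "n_cells": int(grp["cell_id"].nunique()),
        }
    return results


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate -> quantify -> summarize -> estimate -> test, end to end.

    Writes measurements.csv, summaries.csv, effects.json, tests.json,
    trains.json (when train conditions are configured) and run.log under
    ``out_dir``; returns the bundle as a dict.  Byte-identical outputs
    for identical master seeds (the log's timestamps excepted).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        log.info("config: %s", json.dumps(config.to_dict(), default=_json_default))
        log.info("numpy %s, pandas %s", np.__version__, pd.__version__)

        sweeps = simulate_experiment(config)
        log.info("simulated %d sweeps", len(sweeps))
        mdf, sdf = quantify_sweeps(sweeps, config.quantify)
        mdf.to_csv(out / "measurements.csv", index=False)
        sdf.to_csv(out / "summaries.csv", index=False)
        log.info("quantified: %d measurements, %d summaries", len(mdf), len(sdf))

        dataset = effects_mod.PairedDataset.from_tidy(sdf, value="mean_area")
        stats_seed = int(_child_seeds(config.seed + 3, 1)[0])
        summary = effects_mod.estimation_summary(
            dataset, n_boot=config.n_boot, level=config.level, seed=stats_seed
        )
        (out / "effects.json").write_text(
            json.dumps(
                _effects_json(summary, config.n_boot, config.level),
                indent=1,
                default=_json_default,
            )
        )

        tests: dict[str, Any] = {}
        if dataset.n_conditions == 2:
            perm = infer_mod.block_permutation_test(
                dataset, n_mc=config.n_mc, seed=stats_seed
            )
            tests["permutation"] = dataclasses.asdict(perm)
        else:
            fit = infer_mod.fit_repeated_measures(dataset)
            tests["lmm"] = {
                "F": fit.f_statistic,
                "df1": fit.df1,
                "df2": fit.df2,
                "p": fit.p_value,
                "contrasts": [dataclasses.asdict(c) for c in fit.contrasts],
                "between_cell_variance": fit.between_cell_variance,
                "residual_variance": fit.residual_variance,
            }
        (out / "tests.json").write_text(
            json.dumps(tests, indent=1, default=_json_default)
        )

        trains_out = {}
        if config.train_conditions:
            trains_out = run_trains_stage(config, out)
            (out / "trains.json").write_text(
                json.dumps(trains_out, indent=1, default=_json_default)
            )
        log.info("pipeline finished in %.1f s", time.time() - t0)
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return {
        "measurements": mdf,
        "summaries": sdf,
        "effects": summary,
        "tests": tests,
        "trains": trains_out,
    }
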