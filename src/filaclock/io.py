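"""Readers/writers for trace and spectrum tables, configuration and pipelines.

The interchange format for traces is a long-format CSV with required columns
(filament_id, cell_id, position, time_hr, fluorescence) and optional lineage
columns (parent_id, division_time_hr).  All outputs are tidy CSV with units
encoded in column names (``_hr``, ``_per_hr``); configuration is YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .filament import CoherenceResult
from .stats import FilamentTraces
from .stochastic import SpectrumResult

__all__ = [
    "read_traces", "write_traces", "traces_to_long", "traces_from_long",
    "write_spectrum", "read_spectrum", "write_coherence", "read_coherence",
    "load_config", "save_config", "run_pipeline",
]

log = logging.getLogger("filaclock")

REQUIRED_COLUMNS = ("filament_id", "cell_id", "position", "time_hr", "fluorescence")


class TraceSchemaError(ValueError):
    """Raised with the offending column/rows when a trace table is invalid."""


def traces_to_long(traces: FilamentTraces) -> pd.DataFrame:
    n_cells, nt = traces.values.shape
    df = pd.DataFrame({
        "filament_id": np.repeat(traces.filament_id, n_cells * nt),
        "cell_id": np.repeat(traces.cell_ids, nt),
        "position": np.repeat(traces.positions, nt),
        "time_hr": np.tile(traces.time_hr, n_cells),
        "fluorescence": traces.values.ravel(),
    })
    if traces.lineage is not None and len(traces.lineage):
        lin = traces.lineage
        parent = dict(zip(lin.cell_id, lin.parent_id))
        dtime = dict(zip(lin.cell_id, lin.division_time_hr))
        df["parent_id"] = df.cell_id.map(parent)
        df["division_time_hr"] = df.cell_id.map(dtime)
    return df


def traces_from_long(df: pd.DataFrame, filament_id=None) -> FilamentTraces:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"missing required columns: {missing}")
    if filament_id is not None:
        df = df[df.filament_id == filament_id]
    if df.empty:
        raise TraceSchemaError("no rows for the requested filament")
    dup = df.duplicated(subset=["filament_id", "cell_id", "time_hr"])
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise TraceSchemaError(
            f"duplicate (filament_id, cell_id, time_hr) keys at rows {rows}")
    if (df.position < 0).any() or (df.time_hr < 0).any():
        bad = df.index[(df.position < 0) | (df.time_hr < 0)][:5].tolist()
        raise TraceSchemaError(f"negative position or time at rows {bad}")
    wide = df.pivot(index="cell_id", columns="time_hr", values="fluorescence")
    pos = df.groupby("cell_id").position.first()
    wide = wide.loc[pos.sort_values().index]
    lineage = None
    if "parent_id" in df.columns and "division_time_hr" in df.columns:
        lin = (df.groupby("cell_id")[["parent_id", "division_time_hr", "position"]]
               .first().dropna(subset=["parent_id"]).reset_index())
        if len(lin):
            lineage = lin
    return FilamentTraces(values=wide.to_numpy(),
                         time_hr=wide.columns.to_numpy(dtype=float),
                         positions=pos.loc[wide.index].to_numpy(),
                         cell_ids=wide.index.to_numpy(),
                         filament_id=str(df.filament_id.iloc[0]),
                         lineage=lineage)


def write_traces(traces: FilamentTraces | list[FilamentTraces], path) -> None:
    if isinstance(traces, FilamentTraces):
        traces = [traces]
    pd.concat([traces_to_long(t) for t in traces]).to_csv(path, index=False)


def read_traces(path) -> dict[str, FilamentTraces]:
    """Read a long-format CSV into FilamentTraces keyed by filament_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return {fid: traces_from_long(g) for fid, g in df.groupby("filament_id")}


def write_spectrum(spec: SpectrumResult, path) -> None:
    pd.DataFrame({"freq_per_hr": spec.freq_per_hr, "psd": spec.psd}).to_csv(
        path, index=False)


def read_spectrum(path, provenance: str = "periodogram") -> SpectrumResult:
    df = pd.read_csv(path)
    return SpectrumResult(freq_per_hr=df.freq_per_hr.to_numpy(),
                          psd=df.psd.to_numpy(), provenance=provenance)


def write_coherence(coh: CoherenceResult, path) -> None:
    pd.DataFrame({
        "distance_cells": coh.distances,
        "re": coh.values.real, "im": coh.values.imag,
        "magnitude": coh.magnitude,
        "freq_per_hr": coh.freq_per_hr,
    }).to_csv(path, index=False)


def read_coherence(path, provenance: str = "estimated") -> CoherenceResult:
    df = pd.read_csv(path)
    return CoherenceResult(distances=df.distance_cells.to_numpy(),
                           values=df.re.to_numpy() + 1j * df.im.to_numpy(),
                           freq_per_hr=float(df.freq_per_hr.iloc[0]),
                           provenance=provenance)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: dict, out_dir) -> dict:
    """Synthetic end-to-end analysis: generate -> statistics -> spectrum fit
    -> coherence fit -> oscillation detection.

    Deterministic given the seeds in ``config``; every intermediate table is
    written to ``out_dir`` together with a JSON manifest.  Stage failures
    raise with the stage name after persisting partial outputs.
    """
    from . import __version__
    from .fitting import ClockSpectrumModel, CoherenceModel
    from .params import ModelParams
    from .stats import (avg_power_spectrum, coherence_estimate, cv2_series,
                        spatial_autocorr, sync_index)
    from .synth import SynthConfig, synth_filament
    from .tda import detect_oscillation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "stages": []}
    stage = "init"
    try:
        stage = "synth"
        from .filament import CouplingKernel
        syn = dict(config.get("synth", {}))
        if "kernel" in syn:
            syn["kernel"] = CouplingKernel(**syn["kernel"])
        if "params" in syn:
            syn["params"] = ModelParams.from_dict(syn["params"])
        scfg = SynthConfig(**syn)
        log.info("pipeline stage %s: n_cells=%d duration=%.1f hr seed=%d",
                 stage, scfg.n_cells, scfg.duration_hr, seed)
        traces, truth = synth_filament(scfg, seed=seed)
        write_traces(traces, out / "traces.csv")
        manifest["stages"].append(stage)

        stage = "stats"
        R = sync_index(traces, window_hr=tuple(config.get("r_window_hr", (24, 72))))
        np.savetxt(out / "cv2.csv", np.column_stack([traces.time_hr,
                                                     cv2_series(traces)]),
                   delimiter=",", header="time_hr,cv2", comments="")
        mid = traces.values.shape[1] // 2
        g = spatial_autocorr(traces.values[:, mid],
                             max_lag=min(30, traces.n_cells - 1))
        pd.DataFrame({"lag_cells": g.lags, "g": g.g}).to_csv(
            out / "autocorr.csv", index=False)
        manifest["sync_index_R"] = R.R
        manifest["stages"].append(stage)

        stage = "spectrum"
        spec = avg_power_spectrum(traces,
                                  discard_initial_hr=config.get("discard_hr", 24.0))
        write_spectrum(spec, out / "spectrum.csv")
        manifest["stages"].append(stage)

        stage = "spectrum_fit"
        sm = ClockSpectrumModel.from_spectrum(spec, n_tot=scfg.n_tot)
        sfit = sm.fit()
        (out / "spectrum_fit.json").write_text(json.dumps({
            "gamma": sfit.gamma, "kaiA_uM": sfit.kaiA, "sse": sfit.objective,
            "converged": sfit.converged, "band_per_hr": list(sfit.band)}, indent=2))
        manifest["stages"].append(stage)

        stage = "coherence"
        coh = coherence_estimate(traces,
                                 segment_cells=min(35, traces.n_cells))
        write_coherence(coh, out / "coherence.csv")
        cm = CoherenceModel(coh.distances, np.abs(coh.values), sfit.params,
                            n_cells=min(35, traces.n_cells), n_tot=scfg.n_tot)
        cfit = cm.fit()
        (out / "coherence_fit.json").write_text(json.dumps({
            "eps": cfit.eps, "ell_cells": cfit.ell, "sse": cfit.objective,
            "identifiable": cfit.identifiable}, indent=2))
        manifest["stages"].append(stage)

        stage = "tda"
        mu = traces.values.mean(axis=0)
        tda_res = detect_oscillation(mu[traces.time_hr >= 24.0],
                                     traces.time_hr[traces.time_hr >= 24.0],
                                     interp_factor=2)
        (out / "tda.json").write_text(json.dumps({
            "tau_hr": tda_res.tau_hr, "implied_period_hr": tda_res.implied_period_hr,
            "score": tda_res.score, "oscillating": tda_res.oscillating}, indent=2))
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
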