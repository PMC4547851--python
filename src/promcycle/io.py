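"""Readers and writers for the pipeline's on-disk formats.

Trace cohorts travel as long-format CSV (cell_id, time_min, signal) with a
JSON sidecar carrying the sampling interval, calibration and any ground-truth
parameters; posterior chains as one-row-per-iteration CSV; noise reports as
JSON; UMI matrices as MatrixMarket (.mtx) with gene/cell label sidecars.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy import sparse

from .model import PromoterCycleModel
from .rjmcmc import PosteriorChain
from .simulate import CalibrationModel, TraceDataset
from .scnoise import UMICountMatrix

__all__ = [
    "read_trace_table",
    "write_trace_table",
    "write_chain",
    "read_chain",
    "write_umi_matrix",
    "read_umi_matrix",
]

log = logging.getLogger("promcycle")

TRACE_COLUMNS = ("cell_id", "time_min", "signal")


class TraceParseError(ValueError):
    """Malformed trace table (missing columns or non-numeric entries)."""


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_trace_table(dataset: TraceDataset, path) -> None:
    """Long-format CSV plus a JSON sidecar (dt, calibration, ground truth)."""
    frames = []
    for i, s in enumerate(dataset.signals):
        frames.append(pd.DataFrame({
            "cell_id": dataset.cell_ids[i],
            "time_min": dataset.times(i),
            "signal": s,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {"dt": dataset.dt}
    if dataset.calibration is not None:
        meta["calibration"] = dataset.calibration.to_dict()
    gt = dataset.ground_truth
    if gt is not None:
        meta["ground_truth"] = {
            "base_model": gt["base_model"].to_dict() if "base_model" in gt else None,
            "heterogeneity": gt.get("heterogeneity", {}),
            "seed": gt.get("seed"),
        }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trace_table(path) -> TraceDataset:
    """Validated trace dataset from long-format CSV.

    Within-cell sampling must be uniform; a gap (interval larger than 1.5x
    the modal step) splits the trace into separate segments with a logged
    warning.  All cells must share the sampling interval.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"missing column(s) {missing} in {path}")
    for col in ("time_min", "signal"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header + 1-based
            raise TraceParseError(f"non-numeric {col!r} at line {line} of {path}")
        df[col] = coerced

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)

    signals, cell_ids = [], []
    dts = []
    for cell, group in df.groupby("cell_id", sort=False):
        group = group.sort_values("time_min")
        t = group["time_min"].to_numpy(float)
        s = group["signal"].to_numpy(float)
        if len(t) == 1:
            signals.append(s)
            cell_ids.append(str(cell))
            continue
        steps = np.diff(t)
        dt = float(np.median(steps))
        dts.append(dt)
        gaps = np.nonzero(steps > 1.5 * dt)[0]
        if gaps.size:
            log.warning("trace %s has %d gap(s); splitting into %d segments",
                        cell, gaps.size, gaps.size + 1)
        bounds = np.concatenate(([0], gaps + 1, [len(t)]))
        for k in range(len(bounds) - 1):
            seg = slice(bounds[k], bounds[k + 1])
            seg_t = t[seg]
            if len(seg_t) > 1 and not np.allclose(np.diff(seg_t), dt, rtol=1e-6):
                raise TraceParseError(
                    f"non-uniform sampling within a segment of cell {cell}")
            suffix = f"__seg{k}" if len(bounds) > 2 else ""
            signals.append(s[seg])
            cell_ids.append(f"{cell}{suffix}")
    if not signals:
        raise TraceParseError(f"no traces found in {path}")
    dt = meta.get("dt", float(np.median(dts)) if dts else 1.0)
    if dts and not np.allclose(dts, dts[0], rtol=1e-6):
        raise TraceParseError("cells disagree on the sampling interval")
    calibration = None
    if "calibration" in meta:
        calibration = CalibrationModel.from_dict(meta["calibration"])
    return TraceDataset(signals=signals, dt=dt, cell_ids=cell_ids,
                        calibration=calibration)


def write_chain(chain: PosteriorChain, path) -> None:
    df = pd.DataFrame({
        "iteration": np.arange(len(chain)),
        "n": chain.n,
        "k_m": chain.k_m,
        "tau_a": chain.tau_a,
        "T": chain.T,
        "durations": [json.dumps(list(map(float, d))) for d in chain.durations],
        "loglik": chain.loglik,
        "logpost": chain.logpost,
        "move_type": chain.move_type,
        "accepted": chain.accepted.astype(int),
    })
    df.to_csv(path, index=False)
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"seed": chain.seed, "burn_in": chain.burn_in}, fh)


def read_chain(path) -> PosteriorChain:
    df = pd.read_csv(path)
    with open(_sidecar_path(path)) as fh:
        meta = json.load(fh)
    return PosteriorChain(
        n=df["n"].to_numpy(int), k_m=df["k_m"].to_numpy(float),
        tau_a=df["tau_a"].to_numpy(float), T=df["T"].to_numpy(float),
        durations=[np.asarray(json.loads(d)) for d in df["durations"]],
        loglik=df["loglik"].to_numpy(float), logpost=df["logpost"].to_numpy(float),
        move_type=df["move_type"].to_numpy(int),
        accepted=df["accepted"].to_numpy(bool),
        seed=meta["seed"], burn_in=meta["burn_in"])


def write_umi_matrix(matrix: UMICountMatrix, path) -> None:
    """MatrixMarket counts plus gene/cell label sidecar TSVs."""
    path = Path(path)
    mmwrite(str(path), sparse.csr_matrix(matrix.counts))
    genes = pd.DataFrame({"gene": matrix.gene_names, "label": matrix.gene_labels})
    genes.to_csv(path.with_suffix(".genes.tsv"), sep="\t", index=False)
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump({"condition": matrix.condition, "n_cells": matrix.n_cells}, fh)


def read_umi_matrix(path) -> UMICountMatrix:
    path = Path(path)
    counts = np.asarray(mmread(str(path)).todense()).astype(np.int64)
    genes = pd.read_csv(path.with_suffix(".genes.tsv"), sep="\t")
    with open(path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    return UMICountMatrix(counts=counts, gene_labels=list(genes["label"]),
                          gene_names=list(genes["gene"]),
                          condition=meta.get("condition", "cells"))
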