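"""Plain-text input/output: spike rasters, traces, summaries, projections,
and the declarative run-configuration file."""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import yaml

from .connectivity import SparseProjection, build_sparse
from .engine import RunResult, SpikeRecord

__all__ = [
    "write_spike_raster",
    "write_merged_raster",
    "write_traces",
    "write_summary",
    "write_provenance",
    "export_projection_text",
    "import_projection_text",
    "load_run_config",
]


def write_spike_raster(path: str, record: SpikeRecord) -> None:
    """Two-column whitespace-delimited text: time_ms, global_neuron_id."""
    with open(path, "w") as fh:
        for t, gid in zip(record.times, record.global_ids):
            fh.write(f"{t:.6g} {int(gid)}\n")


def write_merged_raster(path: str, records: Mapping[str, SpikeRecord]) -> None:
    """All populations merged into one raster, sorted by time then id."""
    times = np.concatenate([r.times for r in records.values()] or [np.empty(0)])
    gids = np.concatenate(
        [r.global_ids for r in records.values()] or [np.empty(0, dtype=np.int64)])
    order = np.lexsort((gids, times))
    with open(path, "w") as fh:
        for i in order:
            fh.write(f"{times[i]:.6g} {int(gids[i])}\n")


def write_traces(path: str, trace: Mapping) -> None:
    """Delimited table: time plus one column per recorded neuron."""
    ids = trace["ids"]
    with open(path, "w") as fh:
        fh.write("time_ms " + " ".join(f"n{int(i)}" for i in ids) + "\n")
        for t, row in zip(trace["times"], trace["values"]):
            fh.write(f"{t:.6g} " + " ".join(f"{v:.9g}" for v in row) + "\n")


def write_summary(path: str, summary: Mapping) -> None:
    """Key-value text report (nested dicts flattened with dots)."""
    def _emit(fh, prefix, obj):
        if isinstance(obj, Mapping):
            for k, v in obj.items():
                _emit(fh, f"{prefix}{k}.", v) if isinstance(v, Mapping) else fh.write(
                    f"{prefix}{k} = {v}\n")
        else:
            fh.write(f"{prefix.rstrip('.')} = {obj}\n")
    with open(path, "w") as fh:
        _emit(fh, "", summary)


def write_provenance(path: str, entries) -> None:
    """Provenance log: one ``name = value  # source`` line per parameter."""
    with open(path, "w") as fh:
        for name, value, source in entries:
            fh.write(f"{name} = {value}  # {source}\n")


def export_projection_text(path: str, projection, values=None) -> None:
    """Three-column text (pre, post, value) for a sparse or dense projection."""
    with open(path, "w") as fh:
        if projection.kind == "sparse":
            pre_of = np.repeat(np.arange(projection.n_pre), projection.out_degree())
            for s, (i, j) in enumerate(zip(pre_of, projection.post_index)):
                v = values[s] if values is not None else 1.0
                fh.write(f"{int(i)} {int(j)} {v:.9g}\n")
        else:
            ii, jj = np.nonzero(projection.mask)
            for i, j in zip(ii, jj):
                v = values[i, j] if values is not None else 1.0
                fh.write(f"{int(i)} {int(j)} {v:.9g}\n")


def import_projection_text(path: str, n_pre: int, n_post: int):
    """Read a three-column projection file into canonical sparse form.

    Returns ``(SparseProjection, values)``.
    """
    pairs, vals = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            pairs.append((int(parts[0]), int(parts[1])))
            vals.append(float(parts[2]) if len(parts) > 2 else 1.0)
    return build_sparse(n_pre, n_post, pairs, values=np.asarray(vals))


def load_run_config(path: str) -> dict:
    """Load the declarative run configuration (YAML key/value file).

    Recognised keys: ``model`` (kind and its generator arguments), ``dt``,
    ``precision``, ``seed``, ``duration_ms``, ``record`` (population names),
    ``out`` (output directory).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return cfg


def write_run_outputs(outdir: str, model, result: RunResult, summary=None) -> None:
    """Standard output bundle: per-population rasters, merged raster,
    summary report, and the generator's provenance log if present."""
    os.makedirs(outdir, exist_ok=True)
    for name, rec in result.spikes.items():
        write_spike_raster(os.path.join(outdir, f"spikes_{name}.txt"), rec)
    write_merged_raster(os.path.join(outdir, "spikes_all.txt"), result.spikes)
    for (pop, var), trace in result.traces.items():
        write_traces(os.path.join(outdir, f"trace_{pop}_{var}.txt"), trace)
    write_summary(os.path.join(outdir, "summary.txt"), summary or result.summary)
    prov = getattr(model, "metadata", {}).get("provenance")
    if prov:
        write_provenance(os.path.join(outdir, "provenance.txt"), prov)
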