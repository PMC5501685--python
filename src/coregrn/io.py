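"""Readers/writers for the TSV/JSON artifacts and the run configuration.

Formats
-------
Expression TSV: header ``gene<TAB>t<time>_r<rep>...`` (e.g. ``t0_r1``,
``t2.5_r3``); one row per gene.  Replicate counts may differ between time
points (accepted with a warning).

Knockdown TSV: comment lines ``# kd<TAB>target<TAB>fold_change<TAB>time``
describing each experiment, then a header ``gene<TAB><target>...`` and one
row of clipped log2 fold changes per gene.

Prior TSV: header ``regulator<TAB>target[<TAB>sign][<TAB>score]``.

Models, traces and configs are JSON with stable key order and floats fixed
at 10 significant digits, so outputs are diffable and round-trips are
lossless to that precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd

from . import __version__
from .data import ExpressionTimeSeries, KnockdownDataset
from .kinetics import KineticParameters
from .network import NetworkStructure
from .selection import PruningTrace
from .simulate import KnockdownSpec

logger = logging.getLogger(__name__)

_HEADER_RE = re.compile(r"^t(?P<time>-?\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


def _fmt(x: float) -> float:
    """Fix a float at 10 significant digits (deterministic writers)."""
    return float(f"{float(x):.10g}")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _fmt(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- expression -----------------------------------------------------------


def read_expression(path, sigma_mode: str = "pooled") -> ExpressionTimeSeries:
    """Parse the expression TSV dialect; see the module docstring."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first header column must be 'gene'")
    cols: dict[float, list[str]] = {}
    for c in df.columns[1:]:
        m = _HEADER_RE.match(c)
        if not m:
            raise ValueError(f"{path}: malformed sample column {c!r} (want t<time>_r<rep>)")
        cols.setdefault(float(m["time"]), []).append(c)
    genes = df["gene"].tolist()
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene rows {dup}")
    times = sorted(cols)
    n_reps = {len(cols[t]) for t in times}
    if len(n_reps) > 1:
        warnings.warn(
            f"{path}: ragged replicate counts {sorted(n_reps)} across time points",
            stacklevel=2,
        )
    replicates = []
    for t in times:
        block = np.empty((len(genes), len(cols[t])))
        for j, c in enumerate(cols[t]):
            for i, v in enumerate(df[c]):
                try:
                    block[i, j] = float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {v!r} at gene {genes[i]!r}, "
                        f"column {c!r}"
                    ) from None
        replicates.append(block)
    return ExpressionTimeSeries.from_replicates(
        genes, np.array(times), replicates, sigma_mode=sigma_mode
    )


def write_expression(ts: ExpressionTimeSeries, path) -> None:
    if ts.replicates is None:
        raise ValueError("writing requires raw replicates")
    header = ["gene"]
    for t, block in zip(ts.times, ts.replicates):
        header += [f"t{t:g}_r{r + 1}" for r in range(block.shape[1])]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, g in enumerate(ts.genes):
            vals = [f"{_fmt(v):.10g}" for block in ts.replicates for v in block[i]]
            fh.write("\t".join([g] + vals) + "\n")


# -- knockdowns -----------------------------------------------------------


def read_knockdowns(path) -> KnockdownDataset:
    specs = []
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            parts = ln[1:].strip().split("\t")
            if parts and parts[0] == "kd":
                specs.append(KnockdownSpec(parts[1], float(parts[2]), float(parts[3])))
        else:
            body.append(ln)
    if not specs:
        raise ValueError(f"{path}: no '# kd' experiment descriptors found")
    df = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t")
    targets = [s.target_gene for s in specs]
    if list(df.columns[1:]) != targets:
        raise ValueError(
            f"{path}: response columns {list(df.columns[1:])} do not match "
            f"descriptors {targets}"
        )
    genes = tuple(df["gene"])
    responses = df[targets].to_numpy(float).T
    return KnockdownDataset(genes, tuple(specs), responses)


def write_knockdowns(kd: KnockdownDataset, path) -> None:
    with open(path, "w") as fh:
        for s in kd.specs:
            fh.write(f"# kd\t{s.target_gene}\t{_fmt(s.fold_change):.10g}\t{_fmt(s.measurement_time):.10g}\n")
        fh.write("\t".join(["gene"] + [s.target_gene for s in kd.specs]) + "\n")
        for i, g in enumerate(kd.genes):
            vals = [f"{_fmt(v):.10g}" for v in kd.responses[:, i]]
            fh.write("\t".join([g] + vals) + "\n")


# -- prior edges and gene lists -------------------------------------------


def read_prior(path):
    """Edge list TSV -> (edges, signs, scores); signs/scores may be empty."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    for col in ("regulator", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    edges = [(r, t) for r, t in zip(df["regulator"], df["target"])]
    signs = (
        {e: float(s) for e, s in zip(edges, df["sign"])} if "sign" in df.columns else {}
    )
    scores = (
        {e: float(s) for e, s in zip(edges, df["score"])} if "score" in df.columns else {}
    )
    return edges, signs, scores


def write_prior(edges, path, signs=None, scores=None) -> None:
    cols = ["regulator", "target"]
    if signs:
        cols.append("sign")
    if scores:
        cols.append("score")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in edges:
            row = [e[0], e[1]]
            if signs:
                row.append(f"{signs[e]:g}")
            if scores:
                row.append(f"{_fmt(scores[e]):.10g}")
            fh.write("\t".join(row) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


# -- model JSON -----------------------------------------------------------


def _structure_to_dict(s: NetworkStructure) -> dict:
    return {
        "core_genes": list(s.core_genes),
        "peripheral_genes": list(s.peripheral_genes),
        "allowed_edges": [[r, t] for r, t in s.allowed_edges],
        "active_edges": sorted([r, t] for r, t in s.active_edges),
    }


def _structure_from_dict(d: dict) -> NetworkStructure:
    return NetworkStructure(
        tuple(d["core_genes"]),
        tuple(d["peripheral_genes"]),
        tuple((r, t) for r, t in d["allowed_edges"]),
        frozenset((r, t) for r, t in d["active_edges"]),
    )


def _params_to_dict(p: KineticParameters) -> dict:
    return {
        "genes": list(p.genes),
        "lambda": [_fmt(v) for v in p.lambda_],
        "xi": [_fmt(v) for v in p.xi],
        "w": sorted([r, t, _fmt(v)] for (r, t), v in p.w.items()),
    }


def _params_from_dict(d: dict) -> KineticParameters:
    return KineticParameters(
        tuple(d["genes"]),
        np.array(d["lambda"], float),
        np.array(d["xi"], float),
        {(r, t): float(v) for r, t, v in d["w"]},
    )


def trace_to_dict(t: PruningTrace) -> dict:
    return {
        "edge_universe": [[r, g] for r, g in t.edge_universe],
        "removal_order": [[r, g] for r, g in t.removal_order],
        "cost_at_step": [_fmt(v) for v in t.cost_at_step],
        "initial_cost": _fmt(t.initial_cost),
        "stop_index": int(t.stop_index),
        "seed": t.seed,
    }


def trace_from_dict(d: dict, final_structure: NetworkStructure) -> PruningTrace:
    return PruningTrace(
        tuple((r, g) for r, g in d["edge_universe"]),
        tuple((r, g) for r, g in d["removal_order"]),
        np.array(d["cost_at_step"], float),
        float(d["initial_cost"]),
        int(d["stop_index"]),
        final_structure,
        seed=d.get("seed"),
    )


def write_model(model: dict | object, path, config: "RunConfig | None" = None,
                seed: int | None = None) -> None:
    """Serialize a model (structure + parameters + traces + provenance).

    Accepts either a :class:`~coregrn.pipeline.FullModel` or a dict with
    keys ``structure`` and ``params`` (optionally ``core_trace``).
    """
    if hasattr(model, "structure"):
        structure = model.structure
        params = model.params
        core_trace = getattr(model, "core_trace", None)
        diagnostics = getattr(model, "diagnostics", {})
    else:
        structure = model["structure"]
        params = model["params"]
        core_trace = model.get("core_trace")
        diagnostics = model.get("diagnostics", {})
    doc = {
        "format_version": 1,
        "structure": _structure_to_dict(structure),
        "params": _params_to_dict(params),
        "core_trace": trace_to_dict(core_trace) if core_trace is not None else None,
        "diagnostics": _jsonify(diagnostics),
        "provenance": {
            "software_version": __version__,
            "seed": seed,
            "config_hash": config.hash() if config is not None else None,
            "config": asdict(config) if config is not None else None,
        },
    }
    write_json(doc, path)


def read_model(path) -> dict:
    """Read a model JSON back into structure/params/trace objects.

    Structure invariants are re-validated (a hand-edited file with active
    edges outside the prior is rejected).  Version mismatches and missing
    provenance produce warnings, not errors.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != 1:
        warnings.warn(
            f"{path}: model format version {doc.get('format_version')!r} != 1",
            stacklevel=2,
        )
    if not doc.get("provenance"):
        warnings.warn(f"{path}: missing provenance block", stacklevel=2)
    structure = _structure_from_dict(doc["structure"])
    params = _params_from_dict(doc["params"])
    trace = None
    if doc.get("core_trace") is not None:
        trace = trace_from_dict(doc["core_trace"], structure.core_subsystem())
    return {
        "structure": structure,
        "params": params,
        "core_trace": trace,
        "diagnostics": doc.get("diagnostics", {}),
        "provenance": doc.get("provenance", {}),
    }


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults.

    Unknown keys are rejected on load; the resolved config (and its hash)
    is serialized alongside results for provenance.
    """

    rtol: float = 1e-6
    atol: float = 1e-8
    dt: float = 0.1
    sigma_floor: float = 0.05
    sigma_mode: str = "pooled"
    clip_low: float = -2.0
    clip_high: float = 2.0
    alpha: float = 0.05
    criterion: str = "heuristic_std"
    criterion_c: float = 0.05
    population_size: int = 40
    budget: int = 6000
    refit_budget: int = 800
    peripheral_population_size: int = 24
    peripheral_budget: int = 1500
    peripheral_refit_budget: int = 400
    rank_threshold: float | None = None
    n_null_core: int = 1000
    n_null_gene: int = 100
    master_seed: int = 0
    n_workers: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        blob = json.dumps(_jsonify(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
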