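"""Readers and writers for marker matrices, trees, traces and fixtures.

Marker matrices are delimited text (comma or tab, auto-detected) with an
optional header row of site names and entries in {0, 1, NA}.  Trees are
written three ways: a canonical JSON structured dump (the only format
carrying clone parameters), a Newick string with quoted ``'path:count'``
internal labels and branch lengths, and an edge-list CSV with per-node
mass, depth, and genotype call.  Every artifact embeds a provenance
header (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mcmc import McmcConfig, Sample, Trace
from .models import MarkerMatrix, genotype_call
from .simulate import Clone, TrueTree
from .tssb import NodeSnap, snapshot_to_newick

__all__ = ["read_marker_matrix", "write_marker_matrix", "write_tree",
           "read_tree_json", "write_fixture", "read_fixture",
           "write_trace", "read_trace", "format_label", "parse_label",
           "provenance"]


def format_label(label) -> str:
    return "R" if len(label) == 0 else "R." + ".".join(map(str, label))


def parse_label(text: str):
    parts = str(text).split(".")
    if parts[0] != "R":
        raise ValueError(f"malformed clone label {text!r}")
    return tuple(int(p) for p in parts[1:])


def provenance(seed=None, config=None) -> dict:
    meta = {"tool": "clonetree", "version": __version__}
    if seed is not None:
        meta["seed"] = int(seed)
    if config is not None:
        cfg = asdict(config) if is_dataclass(config) else dict(config)
        meta["config"] = cfg
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        meta["config_hash"] = hashlib.sha1(blob).hexdigest()[:12]
    return meta


# -- marker matrices -------------------------------------------------------

def read_marker_matrix(path, kind: str = "methylation") -> MarkerMatrix:
    """Read a delimited 0/1/NA matrix; delimiter and header auto-detected."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty marker matrix file: {path}")
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    sep = "\t" if "\t" in lines[0] else ","
    first = lines[0].split(sep)
    has_header = any(tok.strip() not in ("0", "1", "NA", "") for tok in first)
    rows = []
    for r, line in enumerate(lines[1:] if has_header else lines):
        row = []
        for c, tok in enumerate(line.split(sep)):
            tok = tok.strip()
            if tok == "NA" or tok == "":
                row.append(np.nan)
            elif tok in ("0", "1"):
                row.append(float(tok))
            else:
                raise ValueError(
                    f"non-binary entry {tok!r} at row {r + 1}, "
                    f"column {c + 1} of {path}")
        rows.append(row)
    if not rows:
        raise ValueError(f"no data rows in {path}")
    return MarkerMatrix.from_array(np.array(rows), kind=kind)


def write_marker_matrix(X: MarkerMatrix, path, seed=None) -> None:
    path = Path(path)
    vals = X.values.astype(object)
    vals[X.missing_mask] = "NA"
    header = ",".join(f"site{i + 1}" for i in range(X.n_sites))
    lines = []
    if seed is not None:
        lines.append(f"# {json.dumps(provenance(seed=seed))}")
    lines.append(header)
    lines += [",".join(str(v) for v in row) for row in vals]
    path.write_text("\n".join(lines) + "\n")


# -- trees -----------------------------------------------------------------

def _snap_to_json(snap: dict) -> list:
    out = []
    for label in sorted(snap, key=lambda l: (len(l), l)):
        ns = snap[label]
        out.append({
            "label": list(label),
            "nu": ns.nu,
            "psi": list(ns.psi),
            "theta": None if ns.theta is None else
                     [float(v) for v in ns.theta],
            "branch_length": ns.t,
            "n_assigned": int(ns.n_assigned),
            "pi": float(ns.pi),
        })
    return out


def _snap_from_json(nodes: list) -> dict:
    snap = {}
    for d in nodes:
        label = tuple(d["label"])
        snap[label] = NodeSnap(
            label=label, nu=d["nu"], psi=list(d["psi"]),
            theta=None if d["theta"] is None else np.array(d["theta"]),
            t=d["branch_length"], n_assigned=d["n_assigned"], pi=d["pi"])
    return snap


def write_tree(snap: dict, prefix, eta: float = 1.0, meta=None) -> list:
    """Write a tree snapshot as JSON dump, Newick, and edge-list CSV.

    Returns the list of written paths.  The JSON dump is canonical; the
    edge CSV carries per-node mass, depth and the thresholded genotype
    call.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    doc = {"meta": meta or provenance(), "nodes": _snap_to_json(snap)}
    p_json = prefix.with_suffix(".json")
    p_json.write_text(json.dumps(doc, indent=1) + "\n")
    p_nwk = prefix.with_suffix(".nwk")
    p_nwk.write_text(snapshot_to_newick(snap) + "\n")
    rows = []
    for label in sorted(snap, key=lambda l: (len(l), l)):
        ns = snap[label]
        call = ("" if ns.theta is None else
                "".join(str(int(v)) for v in genotype_call(ns.theta, eta)))
        rows.append({
            "node": format_label(label),
            "parent": "" if label == () else format_label(label[:-1]),
            "depth": len(label), "pi": ns.pi,
            "branch_length": "" if ns.t is None else ns.t,
            "n_assigned": ns.n_assigned, "genotype": call})
    p_csv = prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(p_csv, index=False)
    return [p_json, p_nwk, p_csv]


def read_tree_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    return _snap_from_json(doc["nodes"])


# -- fixtures --------------------------------------------------------------

def write_fixture(fixture: TrueTree, path, meta=None) -> None:
    doc = {
        "meta": meta or provenance(),
        "mode": fixture.mode,
        "clones": [{"label": list(c.label), "frequency": c.frequency,
                    "genotype": list(c.genotype)}
                   for c in fixture.clones],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_fixture(path) -> TrueTree:
    doc = json.loads(Path(path).read_text())
    clones = tuple(Clone(tuple(c["label"]), c["frequency"],
                         tuple(c["genotype"]))
                   for c in doc["clones"])
    return TrueTree(mode=doc["mode"], clones=clones)


# -- traces ----------------------------------------------------------------

def write_trace(trace: Trace, outdir) -> None:
    """Persist a trace directory: per-sample assignments (CSV),
    scalar diagnostics (CSV), tree snapshots (JSON lines), and meta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = provenance(seed=trace.config.seed, config=trace.config)
    meta.update({"kind": trace.kind, "n_obs": trace.n_obs,
                 "n_samples": len(trace)})
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    with open(outdir / "assignments.csv", "w") as fh:
        for s in trace:
            fh.write(",".join(format_label(l) for l in s.labels) + "\n")
    diag = pd.DataFrame({
        "sample": np.arange(len(trace)),
        "complete_data_loglik": [s.cdll for s in trace],
        "n_big_nodes": [s.n_big for s in trace]})
    diag.to_csv(outdir / "diagnostics.csv", index=False)
    with open(outdir / "snapshots.jsonl", "w") as fh:
        for s in trace:
            fh.write(json.dumps({"nodes": _snap_to_json(s.snapshot)}) + "\n")


def read_trace(outdir) -> Trace:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    diag = pd.read_csv(outdir / "diagnostics.csv")
    samples = []
    with open(outdir / "assignments.csv") as fh:
        label_rows = [[parse_label(t) for t in line.strip().split(",")]
                      for line in fh if line.strip()]
    with open(outdir / "snapshots.jsonl") as fh:
        snaps = [_snap_from_json(json.loads(line)["nodes"]) for line in fh]
    for i, (labels, snap) in enumerate(zip(label_rows, snaps)):
        uniq = {}
        codes = np.array([uniq.setdefault(l, len(uniq)) for l in labels])
        samples.append(Sample(
            node_labels=list(uniq), codes=codes, snapshot=snap,
            cdll=float(diag["complete_data_loglik"][i]),
            n_big=int(diag["n_big_nodes"][i])))
    cfg = McmcConfig(**meta["config"]) if "config" in meta else McmcConfig()
    return Trace(samples=samples, n_obs=meta["n_obs"], kind=meta["kind"],
                 config=cfg)
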