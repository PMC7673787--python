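"""Readers and writers for sweep containers and SWC reconstructions.

Two interchangeable sweep containers are supported:

* HDF5 — ``/cells/<cell_id>/sweeps/<sweep_id>/{voltage,current}`` datasets
  with attributes ``dt_ms``, ``protocol_tag`` and any step metadata; cell
  groups carry ``genotype``, ``layer``, ``resting_potential``.
* CSV directory — one file per sweep with header ``t_ms,v_mV,i_pA`` plus a
  ``cell.json`` sidecar holding cell and per-sweep metadata.

All values are converted to canonical units (mV / pA / ms) here and nowhere
else.  Round-trips are lossless to float64 precision.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np

from .core import CellRecording, FormatError, Trace
from .morphology import NeuriteTree, SWCNode

_META_KEYS = ("step_pA", "baseline_ms", "step_ms", "evoked_windows", "ap_peaks_ms")


# ---------------------------------------------------------------------------
# sweep containers
# ---------------------------------------------------------------------------

def write_sweepset(rec: CellRecording, path, format: str = "hdf5") -> None:
    """Write a :class:`CellRecording` to disk.

    ``format`` is ``"hdf5"`` (single file) or ``"csv_dir"`` (directory of
    per-sweep CSV files plus a JSON sidecar).
    """
    path = Path(path)
    if format == "hdf5":
        _write_hdf5(rec, path)
    elif format == "csv_dir":
        _write_csv_dir(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sweepset(path, format: str | None = None) -> CellRecording:
    """Read a :class:`CellRecording` written by :func:`write_sweepset`."""
    path = Path(path)
    if format is None:
        format = "csv_dir" if path.is_dir() else "hdf5"
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv_dir":
        return _read_csv_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _meta_to_attrs(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if k in ("evoked_windows", "ap_peaks_ms"):
            out[k] = json.dumps(v)
        else:
            out[k] = v
    return out


def _attrs_to_meta(attrs) -> dict:
    meta = {}
    for k in _META_KEYS:
        if k in attrs:
            v = attrs[k]
            if k in ("evoked_windows", "ap_peaks_ms"):
                meta[k] = json.loads(v)
            else:
                meta[k] = float(v)
    return meta


def _write_hdf5(rec: CellRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        cells = f.require_group("cells")
        g = cells.create_group(rec.cell_id)
        g.attrs["genotype"] = rec.genotype
        g.attrs["layer"] = rec.layer
        g.attrs["resting_potential"] = rec.resting_potential
        sweeps = g.create_group("sweeps")
        for tr in rec.sweeps:
            sg = sweeps.create_group(tr.sweep_id)
            sg.create_dataset("voltage", data=tr.voltage)
            sg.create_dataset("current", data=tr.current)
            sg.attrs["dt_ms"] = tr.time_step
            sg.attrs["protocol_tag"] = tr.protocol_tag
            for k, v in _meta_to_attrs(tr.meta).items():
                sg.attrs[k] = v


def _read_hdf5(path: Path) -> CellRecording:
    with h5py.File(path, "r") as f:
        if "cells" not in f:
            raise FormatError(f"{path}: no /cells group")
        cell_ids = list(f["cells"])
        if len(cell_ids) != 1:
            raise FormatError(
                f"{path}: expected exactly one cell group, found {len(cell_ids)}"
            )
        cid = cell_ids[0]
        g = f["cells"][cid]
        rec = CellRecording(
            cell_id=cid,
            genotype=str(g.attrs.get("genotype", "WT")),
            layer=str(g.attrs.get("layer", "unknown")),
            resting_potential=float(g.attrs.get("resting_potential", -65.0)),
        )
        for sid in g["sweeps"]:
            sg = g["sweeps"][sid]
            if "voltage" not in sg or "current" not in sg:
                raise FormatError(f"{path}: sweep {sid!r} missing voltage or current")
            rec.sweeps.append(
                Trace(
                    time_step=float(sg.attrs["dt_ms"]),
                    voltage=sg["voltage"][...],
                    current=sg["current"][...],
                    sweep_id=sid,
                    protocol_tag=str(sg.attrs["protocol_tag"]),
                    meta=_attrs_to_meta(sg.attrs),
                )
            )
    rec.sweeps = rec.sorted_sweeps()
    return rec


def _write_csv_dir(rec: CellRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "cell_id": rec.cell_id,
        "genotype": rec.genotype,
        "layer": rec.layer,
        "resting_potential": rec.resting_potential,
        "sweeps": {},
    }
    for tr in rec.sweeps:
        fname = f"{tr.sweep_id}.csv"
        t = tr.t_ms
        arr = np.column_stack([t, tr.voltage, tr.current])
        np.savetxt(
            path / fname,
            arr,
            delimiter=",",
            header="t_ms,v_mV,i_pA",
            comments="",
            fmt="%.12g",
        )
        sidecar["sweeps"][tr.sweep_id] = {
            "file": fname,
            "dt_ms": tr.time_step,
            "protocol_tag": tr.protocol_tag,
            "meta": tr.meta,
        }
    (path / "cell.json").write_text(json.dumps(sidecar, indent=1))


def _read_csv_dir(path: Path) -> CellRecording:
    sidecar_path = path / "cell.json"
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing cell.json sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    rec = CellRecording(
        cell_id=sidecar["cell_id"],
        genotype=sidecar.get("genotype", "WT"),
        layer=sidecar.get("layer", "unknown"),
        resting_potential=float(sidecar.get("resting_potential", -65.0)),
    )
    for sid, info in sidecar["sweeps"].items():
        fpath = path / info["file"]
        if not fpath.exists():
            raise FormatError(f"{fpath}: sweep file listed in sidecar is missing")
        with open(fpath) as fh:
            header = fh.readline().strip().split(",")
        if header != ["t_ms", "v_mV", "i_pA"]:
            raise FormatError(f"{fpath}: header must be t_ms,v_mV,i_pA, got {header}")
        try:
            arr = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as e:
            raise FormatError(f"{fpath}: malformed rows ({e})") from None
        if arr.shape[1] != 3:
            raise FormatError(f"{fpath}: expected 3 columns, got {arr.shape[1]}")
        t, v, i = arr[:, 0], arr[:, 1], arr[:, 2]
        dt = float(info["dt_ms"])
        if len(t) > 1:
            dts = np.diff(t)
            if not np.allclose(dts, dt, rtol=0, atol=1e-6):
                raise FormatError(f"{fpath}: non-uniform sampling in sweep {sid!r}")
        rec.sweeps.append(
            Trace(
                time_step=dt,
                voltage=v,
                current=i,
                sweep_id=sid,
                protocol_tag=info["protocol_tag"],
                meta=info.get("meta", {}),
            )
        )
    rec.sweeps = rec.sorted_sweeps()
    return rec


# ---------------------------------------------------------------------------
# SWC reconstructions
# ---------------------------------------------------------------------------

_SWC_TYPE = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}
_SWC_CODE = {"soma": 1, "axon": 2, "dendrite": 3}


def read_swc(path) -> NeuriteTree:
    """Parse a standard 7-column SWC file into a :class:`NeuriteTree`.

    Raises :class:`FormatError` on duplicate ids, unknown parents, cycles,
    or a missing root.
    """
    path = Path(path)
    nodes: dict[int, SWCNode] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            nid, code, x, y, z, r, parent = parts
            nid, code, parent = int(nid), int(code), int(parent)
            if nid in nodes:
                raise FormatError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = SWCNode(
                id=nid,
                type=_SWC_TYPE.get(code, "dendrite"),
                x=float(x),
                y=float(y),
                z=float(z),
                radius=float(r),
                parent=parent,
            )
    roots = [n for n in nodes.values() if n.parent == -1]
    if len(roots) != 1:
        raise FormatError(f"{path}: expected exactly one root, found {len(roots)}")
    for n in nodes.values():
        if n.parent != -1 and n.parent not in nodes:
            raise FormatError(f"{path}: node {n.id} has unknown parent {n.parent}")
    # cycle check by walking to root from each node
    for n in nodes.values():
        seen = set()
        cur = n
        while cur.parent != -1:
            if cur.id in seen:
                raise FormatError(f"{path}: cycle involving node {cur.id}")
            seen.add(cur.id)
            cur = nodes[cur.parent]
    return NeuriteTree(nodes=nodes, root_id=roots[0].id)


def write_swc(tree: NeuriteTree, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(tree.nodes):
            n = tree.nodes[nid]
            fh.write(
                f"{n.id} {_SWC_CODE[n.type]} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {n.parent}\n"
            )
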