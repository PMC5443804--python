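"""On-disk formats: TSV curves/traces, plain-matrix topographs, PDB models.

All formats are plain text for portability and testability.  Tabular
files carry '#'-prefixed metadata headers including a mandatory
``n_rows`` count, which lets every reader reject silently truncated
files.  Unit convention at the I/O boundary: lengths nm, forces pN,
times ms.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from . import __version__
from .dpca import DihedralTrajectory
from .dwell import IntensityTrace
from .errors import FormatError
from .force import ForceDistanceCurve
from .mcpull import CGModel, Contact
from .morphology import Topograph

__all__ = [
    "read_curve", "write_curve",
    "read_trace", "write_trace",
    "read_topograph", "write_topograph",
    "read_cg_model", "write_cg_model",
    "read_dihedrals", "write_dihedrals",
    "write_result_json", "config_hash",
]


# ---------------------------------------------------------------------------
# generic '#'-header TSV
# ---------------------------------------------------------------------------

def _write_tsv(path, meta: dict, columns: dict):
    path = Path(path)
    n_rows = len(next(iter(columns.values())))
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    lines.append(f"# n_rows: {n_rows}")
    lines.append("\t".join(columns))
    data = np.column_stack([np.asarray(v, dtype=float) for v in columns.values()])
    body = "\n".join("\t".join(f"{x:.10g}" for x in row) for row in data)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _read_tsv(path, required_meta):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    meta, rows, header = {}, [], None
    with open(path) as fh:  # newline=None: both Unix and Windows endings
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif header is None:
                header = line.split("\t")
            else:
                rows.append([float(v) for v in line.split("\t")])
    for key in list(required_meta) + ["n_rows"]:
        if key not in meta:
            raise FormatError(f"{path}: missing metadata key '{key}'")
    n_expected = int(meta["n_rows"])
    if len(rows) != n_expected:
        raise FormatError(
            f"{path}: truncated file (expected {n_expected} rows, found {len(rows)})")
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header or [])))
    return meta, header, data


# ---------------------------------------------------------------------------
# force-distance curves
# ---------------------------------------------------------------------------

def write_curve(curve: ForceDistanceCurve, path):
    _write_tsv(path,
               {"id": curve.id,
                "retraction_speed": curve.retraction_speed,
                "spring_constant": curve.spring_constant},
               {"distance_nm": curve.distance, "force_pN": curve.force})


def read_curve(path) -> ForceDistanceCurve:
    meta, header, data = _read_tsv(path, ["retraction_speed", "spring_constant"])
    if header != ["distance_nm", "force_pN"]:
        raise FormatError(f"{path}: expected columns distance_nm, force_pN")
    return ForceDistanceCurve(
        distance=data[:, 0], force=data[:, 1],
        retraction_speed=float(meta["retraction_speed"]),
        spring_constant=float(meta["spring_constant"]),
        id=meta.get("id", ""),
    )


# ---------------------------------------------------------------------------
# intensity traces
# ---------------------------------------------------------------------------

def write_trace(trace: IntensityTrace, path):
    _write_tsv(path, {"id": trace.id, "frame_ms": trace.frame_ms},
               {"intensity": trace.intensity})


def read_trace(path) -> IntensityTrace:
    meta, header, data = _read_tsv(path, ["frame_ms"])
    if header != ["intensity"]:
        raise FormatError(f"{path}: expected a single 'intensity' column")
    return IntensityTrace(intensity=data[:, 0], frame_ms=float(meta["frame_ms"]),
                          id=meta.get("id", ""))


# ---------------------------------------------------------------------------
# topographs: whitespace matrix + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_topograph(topo: Topograph, path):
    path = Path(path)
    np.savetxt(path, topo.heights, fmt="%.6g")
    _sidecar(path).write_text(json.dumps(
        {"pixel_nm": topo.pixel_nm, "id": topo.id,
         "shape": list(topo.heights.shape)}))


def read_topograph(path) -> Topograph:
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    if "pixel_nm" not in meta:
        raise FormatError(f"{sidecar}: missing 'pixel_nm'")
    if float(meta["pixel_nm"]) <= 0:
        raise FormatError(f"{sidecar}: pixel_nm must be positive")
    heights = np.loadtxt(path, ndmin=2)
    if "shape" in meta and list(heights.shape) != list(meta["shape"]):
        raise FormatError(
            f"{path}: truncated matrix (expected shape {meta['shape']}, "
            f"found {list(heights.shape)})")
    bad = np.argwhere(~np.isfinite(heights))
    if bad.size:
        r, c = bad[0]
        raise FormatError(f"{path}: non-finite height at row {r}, col {c}")
    return Topograph(heights=heights, pixel_nm=float(meta["pixel_nm"]),
                     id=meta.get("id", ""))


# ---------------------------------------------------------------------------
# coarse-grained models: Calpha PDB + JSON contact list
# ---------------------------------------------------------------------------

def write_cg_model(model: CGModel, pdb_path, json_path):
    n = model.n_beads
    atoms = bst.AtomArray(n)
    atoms.coord = np.asarray(model.coords, dtype=float) * 10.0  # nm -> Angstrom
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.res_name = np.array(["GLY"] * n)
    chain_letters = "ABCDEFGH"
    atoms.chain_id = np.array([chain_letters[int(c)] for c in model.chain_of])
    res_ids = np.zeros(n, dtype=int)
    for chain in np.unique(model.chain_of):
        sel = model.chain_of == chain
        res_ids[sel] = np.arange(1, sel.sum() + 1)
    atoms.res_id = res_ids
    pdb = bpdb.PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(pdb_path))
    Path(json_path).write_text(json.dumps({
        "bonds": [[i, j, r0, k] for i, j, r0, k in model.bonds],
        "contacts": [{"i": c.i, "j": c.j, "r0": c.r0, "depth": c.depth,
                      "cls": c.cls} for c in model.contacts],
        "pulling_groups": list(model.pulling_groups)
        if model.pulling_groups is not None else None,
    }, indent=1))


def read_cg_model(pdb_path, json_path) -> CGModel:
    pdb_path, json_path = Path(pdb_path), Path(json_path)
    if not json_path.exists():
        raise FormatError(f"{pdb_path}: missing contact list {json_path.name}")
    pdb = bpdb.PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    coords = np.asarray(ca.coord, dtype=float) / 10.0  # Angstrom -> nm
    chain_ids = {cid: k for k, cid in enumerate(dict.fromkeys(ca.chain_id))}
    chain_of = np.array([chain_ids[c] for c in ca.chain_id])
    meta = json.loads(json_path.read_text())
    contacts = [Contact(**c) for c in meta["contacts"]]
    bonds = [tuple(b) for b in meta["bonds"]]
    pulling = tuple(meta["pulling_groups"]) if meta["pulling_groups"] else None
    return CGModel(coords=coords, chain_of=chain_of, bonds=bonds,
                   contacts=contacts, pulling_groups=pulling)


# ---------------------------------------------------------------------------
# dihedral tables
# ---------------------------------------------------------------------------

def write_dihedrals(traj: DihedralTrajectory, path):
    labels = ";".join(f"{res}:{name}" for res, name in traj.labels)
    terminal = "".join("1" if t else "0" for t in traj.terminal_mask)
    _write_tsv(path, {"labels": labels, "terminal_mask": terminal},
               {f"a{k}": traj.angles[:, k] for k in range(traj.angles.shape[1])})


def read_dihedrals(path) -> DihedralTrajectory:
    meta, header, data = _read_tsv(path, ["labels", "terminal_mask"])
    labels = []
    for item in meta["labels"].split(";"):
        res, _, name = item.partition(":")
        labels.append((int(res), name))
    mask = np.array([ch == "1" for ch in meta["terminal_mask"]])
    return DihedralTrajectory(angles=data, labels=labels, terminal_mask=mask)


# ---------------------------------------------------------------------------
# result provenance
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_result_json(path, results: dict, config: dict, seed=None):
    """Write results with the provenance contract: config hash, seed, version."""
    payload = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "results": results,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))
    return payload


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
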