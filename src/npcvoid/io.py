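"""File I/O: voxel grids (MRC/CCP4, OpenDX), mesh ensembles (PDB, XYZ),
and the tabular profile formats (TSV with JSON sidecars).

Grid conventions: the in-memory origin is the *corner* of the box and voxel
(i,j,k) is centered at origin + (i+1/2)·spacing.  CCP4 files carry the corner
origin in the MRC origin header words; DX files store the center of the
first voxel (the OpenDX convention).  Infinite sentinel values are clamped
to ±1e30 on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from gridData import Grid as _DXGrid

from .grids import GridSpec, ScalarGrid3D
from .mesh import BeadChain, MeshConfiguration
from .pmf import PMFProfile
from .voids import EnsembleOccupancy, OccupancyProfile

__all__ = [
    "write_grid_mrc", "read_grid_mrc", "write_grid_dx", "read_grid_dx",
    "write_grid", "read_grid",
    "write_ensemble_xyz", "read_ensemble_xyz",
    "write_ensemble_pdb", "read_ensemble_pdb",
    "write_occupancy_tsv", "read_occupancy_tsv",
    "write_pmf_tsv", "read_pmf_tsv",
    "write_percolation_tsv",
    "convert",
]

_CLAMP = 1e30


def _clamped(values: np.ndarray) -> np.ndarray:
    return np.clip(np.nan_to_num(values, posinf=_CLAMP, neginf=-_CLAMP),
                   -_CLAMP, _CLAMP)


def write_grid_mrc(grid: ScalarGrid3D, path) -> Path:
    """Write as CCP4/MRC mode-2 map; corner origin goes in header words 50-52."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(_clamped(grid.values).astype(np.float32))
    sp = grid.spacing
    sh = grid.shape
    m.grid.unit_cell = gemmi.UnitCell(sh[0] * sp[0], sh[1] * sp[1], sh[2] * sp[2],
                                      90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.find_spacegroup_by_number(1)
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))
    return Path(path)


def read_grid_mrc(path, unit_tag: str = "kcal/mol") -> ScalarGrid3D:
    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, copy=True).astype(np.float64)
    cell = m.grid.unit_cell
    shape = values.shape
    spacing = (cell.a / shape[0], cell.b / shape[1], cell.c / shape[2])
    origin = tuple(float(m.header_float(w)) for w in (50, 51, 52))
    return ScalarGrid3D(GridSpec(origin, spacing, shape), values, unit_tag)


def write_grid_dx(grid: ScalarGrid3D, path) -> Path:
    """Write as OpenDX; the DX origin is the center of the first voxel."""
    g = _DXGrid(_clamped(grid.values),
                origin=np.asarray(grid.origin) + 0.5 * grid.spacing,
                delta=grid.spacing)
    g.export(str(path), typequote="")
    return Path(path)


def read_grid_dx(path, unit_tag: str = "kcal/mol") -> ScalarGrid3D:
    g = _DXGrid(str(path))
    delta = np.atleast_1d(np.asarray(g.delta, float))
    if delta.ndim == 2:
        delta = np.diag(delta)
    if delta.size == 1:
        delta = np.repeat(delta, 3)
    origin = np.asarray(g.origin, float) - 0.5 * delta
    return ScalarGrid3D(
        GridSpec(tuple(origin), tuple(delta), g.grid.shape),
        np.asarray(g.grid, float), unit_tag,
    )


def write_grid(grid: ScalarGrid3D, path) -> Path:
    """Write by extension; the unit tag travels in a small JSON sidecar
    (neither MRC nor DX has a native slot for it)."""
    path = Path(path)
    if path.suffix.lower() in (".mrc", ".ccp4", ".map"):
        out = write_grid_mrc(grid, path)
    elif path.suffix.lower() == ".dx":
        out = write_grid_dx(grid, path)
    else:
        raise ValueError(f"unsupported grid format {path.suffix!r}")
    with open(str(path) + ".json", "w") as fh:
        json.dump({"unit_tag": grid.unit_tag}, fh)
    return out


def read_grid(path, unit_tag: str | None = None) -> ScalarGrid3D:
    path = Path(path)
    if unit_tag is None:
        try:
            with open(str(path) + ".json") as fh:
                unit_tag = json.load(fh).get("unit_tag", "kcal/mol")
        except FileNotFoundError:
            unit_tag = "kcal/mol"
    if path.suffix.lower() in (".mrc", ".ccp4", ".map"):
        return read_grid_mrc(path, unit_tag)
    if path.suffix.lower() == ".dx":
        return read_grid_dx(path, unit_tag)
    raise ValueError(f"unsupported grid format {path.suffix!r}")


# ---------------------------------------------------------------------------
# mesh ensembles

def write_ensemble_xyz(ensemble, directory, stem: str = "frame") -> Path:
    """One whitespace table per frame (x y z species chain), plus an index file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for mesh in ensemble:
        fn = directory / f"{stem}_{mesh.frame_id:05d}.xyz"
        with open(fn, "w") as fh:
            fh.write(f"# frame {mesh.frame_id}\n# x_A y_A z_A species chain\n")
            for ci, ch in enumerate(mesh.chains):
                for p in ch.positions:
                    fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {ch.species} {ci}\n")
        index.append({"frame_id": mesh.frame_id, "file": fn.name,
                      "n_chains": len(mesh.chains), "n_beads": mesh.n_beads})
    with open(directory / f"{stem}_index.json", "w") as fh:
        json.dump(index, fh, indent=1)
    return directory


def read_ensemble_xyz(directory, stem: str = "frame"):
    directory = Path(directory)
    with open(directory / f"{stem}_index.json") as fh:
        index = json.load(fh)
    ensemble = []
    for entry in index:
        rows = []
        with open(directory / entry["file"]) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                x, y, z, species, chain = line.split()
                rows.append((float(x), float(y), float(z), species, int(chain)))
        chains = []
        if rows:
            arr = np.array([(r[0], r[1], r[2]) for r in rows])
            cids = np.array([r[4] for r in rows])
            species = np.array([r[3] for r in rows])
            for ci in np.unique(cids):
                sel = cids == ci
                chains.append(BeadChain(species=str(species[sel][0]),
                                        positions=arr[sel]))
        ensemble.append(MeshConfiguration(chains=chains,
                                          frame_id=int(entry["frame_id"])))
    return ensemble


def write_ensemble_pdb(ensemble, path) -> Path:
    """Multi-model PDB, one CA-style bead per residue; chains cycle A-Z0-9."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    arrays = []
    for mesh in ensemble:
        n = mesh.n_beads
        arr = struc.AtomArray(n)
        k = 0
        for ci, ch in enumerate(mesh.chains):
            for ri, p in enumerate(ch.positions):
                arr.coord[k] = p
                arr.chain_id[k] = ids[ci % len(ids)]
                arr.res_id[k] = ri + 1
                arr.res_name[k] = "GLY"
                arr.atom_name[k] = "CA"
                arr.element[k] = "C"
                k += 1
        arrays.append(arr)
    pf = pdb.PDBFile()
    pf.set_structure(struc.stack(arrays))
    pf.write(str(path))
    return Path(path)


def read_ensemble_pdb(path):
    """Frames back from a multi-model PDB (species labels are not preserved)."""
    import biotite.structure.io.pdb as pdb

    pf = pdb.PDBFile.read(str(path))
    stack = pf.get_structure()
    ensemble = []
    for f in range(stack.stack_depth()):
        arr = stack[f]
        chains = []
        for cid in np.unique(arr.chain_id):
            sel = arr.chain_id == cid
            chains.append(BeadChain(species=str(cid), positions=arr.coord[sel]))
        ensemble.append(MeshConfiguration(chains=chains, frame_id=f))
    return ensemble


# ---------------------------------------------------------------------------
# tabular profiles

def write_occupancy_tsv(occ, path) -> Path:
    if isinstance(occ, EnsembleOccupancy):
        df = pd.DataFrame({"z": occ.z_centers, "h": occ.h_mean,
                           "h_sem": occ.h_sem, "A": occ.A_mean})
        meta = {"n_frames": occ.n_frames, "l_c": occ.l_c, "A_c": occ.A_c,
                "slab_height": occ.slab_height}
    else:
        df = pd.DataFrame({"z": occ.z_centers, "h": occ.h,
                           "P1": occ.P1, "A": occ.A})
        meta = {"frame_id": occ.frame_id, "l_c": occ.l_c, "A_c": occ.A_c,
                "slab_height": occ.slab_height}
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)
    return Path(path)


def read_occupancy_tsv(path):
    df = pd.read_csv(path, sep="\t")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    if "h_sem" in df.columns:
        return EnsembleOccupancy(
            z_centers=df["z"].to_numpy(), h_mean=df["h"].to_numpy(),
            h_sem=df["h_sem"].to_numpy(), n_frames=meta["n_frames"],
            l_c=meta["l_c"], A_c=meta["A_c"],
            slab_height=meta.get("slab_height"),
        )
    n = df["h"].to_numpy() / np.where(df["P1"].to_numpy() > 0,
                                      df["P1"].to_numpy(), np.nan)
    return OccupancyProfile(
        z_centers=df["z"].to_numpy(), h=df["h"].to_numpy(),
        n_total=np.nan_to_num(n), l_c=meta["l_c"], A_c=meta["A_c"],
        slab_height=meta.get("slab_height"), frame_id=meta.get("frame_id", 0),
    )


def write_pmf_tsv(profile: PMFProfile, path, metadata: dict | None = None) -> Path:
    df = pd.DataFrame({
        "z": profile.z,
        "F_kBT": _clamped(profile.F),
        "F_kcal": _clamped(profile.F_kcal),
        "stderr": (_clamped(profile.stderr) if profile.stderr is not None
                   else np.zeros_like(profile.z)),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    meta = {"source": profile.source, "asymmetry": profile.asymmetry}
    meta.update(metadata or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)
    return Path(path)


def read_pmf_tsv(path) -> PMFProfile:
    df = pd.read_csv(path, sep="\t")
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    F = df["F_kBT"].to_numpy().copy()
    F[F >= _CLAMP] = np.inf
    return PMFProfile(z=df["z"].to_numpy(), F=F,
                      source=meta.get("source", "void"),
                      stderr=df["stderr"].to_numpy() if "stderr" in df else None,
                      asymmetry=meta.get("asymmetry"))


def write_percolation_tsv(curve, path) -> Path:
    df = pd.DataFrame({
        "R_p": curve.probe_radii, "p_open": curve.p_open,
        "n": np.full(len(curve.probe_radii), curve.n_frames),
        "ci_lo": curve.ci_lo, "ci_hi": curve.ci_hi,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return Path(path)


# ---------------------------------------------------------------------------
# conversion

def convert(input_path, output_path) -> Path:
    """Format conversion keyed on file extensions.

    Supported: grid formats (.mrc/.ccp4/.map <-> .dx), TSV profile -> .json,
    multi-model .pdb -> per-frame .xyz directory and back.
    """
    src, dst = Path(input_path), Path(output_path)
    grid_ext = (".mrc", ".ccp4", ".map", ".dx")
    if src.suffix.lower() in grid_ext and dst.suffix.lower() in grid_ext:
        return write_grid(read_grid(src), dst)
    if src.suffix.lower() == ".tsv" and dst.suffix.lower() == ".json":
        df = pd.read_csv(src, sep="\t")
        with open(dst, "w") as fh:
            json.dump({c: df[c].tolist() for c in df.columns}, fh, indent=1)
        return dst
    if src.suffix.lower() == ".pdb" and dst.suffix == "":
        return write_ensemble_xyz(read_ensemble_pdb(src), dst)
    if src.is_dir() and dst.suffix.lower() == ".pdb":
        return write_ensemble_pdb(read_ensemble_xyz(src), dst)
    raise ValueError(f"unsupported conversion {src.suffix!r} -> {dst.suffix!r}")
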