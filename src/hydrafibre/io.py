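"""Reading and writing MD structure/trajectory files.

Supported formats: PDB (CRYST1 + ATOM/HETATM), GRO, a multi-frame extended
XYZ dialect whose comment line carries the box (``box <a> <b> <c> [time <t>]``)
and CHARMM/NAMD 32-bit DCD.  PDB/GRO/DCD go through MDAnalysis; the XYZ
dialect and the parallel velocity stream are native to this package.

Residue names are mapped to group tags through a configurable mapping
(:data:`hydrafibre.core.DEFAULT_GROUP_MAP`); molecule ids default to one
molecule per residue unless bond connectivity says otherwise.
"""

from __future__ import annotations

import os
import warnings
from typing import Optional, Sequence

import numpy as np

from .core import Atom, DEFAULT_GROUP_MAP, Frame, Topology, Trajectory
from .units import element_mass


class FileFormatError(ValueError):
    """Malformed or unsupported input file."""


_AMINO = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
          "HSD", "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO",
          "SER", "THR", "TRP", "TYR", "VAL"}


def _group_for_residue(resname: str, group_map: Optional[dict]) -> str:
    table = DEFAULT_GROUP_MAP if group_map is None else group_map
    r = resname.strip().upper()
    if r in table:
        return table[r]
    if r in _AMINO:
        return "hydrophilic_head"
    return "other"


def _guess_element(name: str, resname: str) -> str:
    n = name.strip()
    if not n:
        return "C"
    # strip leading digits (e.g. 1HB) then take the leading letter;
    # two-letter elements in this package's systems are rare
    while n and n[0].isdigit():
        n = n[1:]
    if not n:
        return "C"
    up = n.upper()
    for two in ("CL", "NA", "MG"):
        if up.startswith(two):
            return two
    return up[0]


def _infer_format(path: str, format: Optional[str]) -> str:
    if format:
        return format.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "gro", "xyz", "dcd"):
        return "xyz-multi" if ext == "xyz" else ext
    raise FileFormatError(f"cannot infer format of {path!r}; pass format=")


# ---------------------------------------------------------------------------
# structure (topology + one frame)
# ---------------------------------------------------------------------------

def read_structure(path, format=None, group_map=None, box=None,
                   velocities=None):
    """Read a single-frame structure file into (Topology, Frame).

    Parameters
    ----------
    path : str
    format : {'pdb', 'gro', 'xyz'}, optional (inferred from extension)
    group_map : dict, optional
        residue name → group tag; defaults to the package mapping.
    box : sequence of 3 floats, optional
        override when the file carries no box information.
    """
    fmt = _infer_format(path, format)
    if fmt in ("xyz", "xyz-multi"):
        frames, elements = _read_xyz_frames(path, box_override=box)
        if not frames:
            raise FileFormatError(f"{path}: no frames found")
        top = _topology_from_elements(elements, group_map)
        return top, frames[0]
    if fmt == "pdb":
        _prevalidate_pdb(path)
    elif fmt == "gro":
        _prevalidate_gro(path)
    else:
        raise FileFormatError(f"unsupported structure format {fmt!r}")

    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    coords = u.atoms.positions.astype(float)
    dims = u.dimensions
    if dims is None or np.all(dims[:3] == 0):
        if box is None:
            raise FileFormatError(
                f"{path}: no box information (CRYST1/box line); pass box=")
        edges = np.asarray(box, dtype=float)
    else:
        if not np.allclose(dims[3:], 90.0):
            raise FileFormatError(
                f"{path}: triclinic boxes are not supported (angles {dims[3:]})")
        edges = dims[:3].astype(float)

    atoms = []
    for k, a in enumerate(u.atoms):
        resname = str(a.resname) if hasattr(a, "resname") else "UNK"
        try:
            element = str(a.element).strip() or _guess_element(a.name, resname)
        except Exception:
            element = _guess_element(str(a.name), resname)
        atoms.append(Atom(
            atom_id=k,
            name=str(a.name),
            element=element,
            mass=element_mass(element),
            residue_name=resname,
            residue_index=int(a.resid),
            molecule_id=int(a.residue.ix),
            group_tag=_group_for_residue(resname, group_map),
        ))
    vel = None
    if velocities is not None:
        vel = np.asarray(velocities, dtype=float)
    frame = Frame(time=0.0, box=edges, coordinates=coords, velocities=vel)
    return Topology(atoms), frame


def _prevalidate_pdb(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise FileFormatError(
                        f"{path}:{lineno}: truncated {rec} record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise FileFormatError(
                        f"{path}:{lineno}: malformed coordinates in {rec} record")


def _prevalidate_gro(path):
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise FileFormatError(f"{path}: too short for GRO")
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise FileFormatError(f"{path}:2: malformed atom count")
    if len(lines) < n + 3:
        raise FileFormatError(f"{path}: expected {n} atom lines")
    for k in range(n):
        line = lines[2 + k]
        if len(line.rstrip("\n")) < 44:
            raise FileFormatError(f"{path}:{3 + k}: truncated atom record")
        try:
            float(line[20:28]); float(line[28:36]); float(line[36:44])
        except ValueError:
            raise FileFormatError(f"{path}:{3 + k}: malformed coordinates")


def write_structure(path, topology: Topology, frame: Frame, format=None):
    """Write a (Topology, Frame) pair to PDB, GRO or extended XYZ."""
    fmt = _infer_format(path, format)
    if fmt in ("xyz", "xyz-multi"):
        with open(path, "w") as fh:
            _write_xyz_block(fh, topology.elements, frame)
        return
    import MDAnalysis as mda
    u = _mda_universe(topology, frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def _mda_universe(topology: Topology, frame: Frame):
    import MDAnalysis as mda
    n = topology.n_atoms
    resids_key = [(int(m), int(r)) for m, r in
                  zip(topology.molecule_ids, topology.residue_indices)]
    uniq = sorted(set(resids_key))
    res_index = {key: i for i, key in enumerate(uniq)}
    atom_res = np.array([res_index[k] for k in resids_key])
    resnames = [None] * len(uniq)
    resids = [None] * len(uniq)
    for k, key in zip(range(n), resids_key):
        resnames[res_index[key]] = str(topology.residue_names[k])
        resids[res_index[key]] = int(topology.residue_indices[k])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=len(uniq),
                               atom_resindex=atom_res, trajectory=True)
        u.add_TopologyAttr("names", [str(x) for x in topology.names])
        u.add_TopologyAttr("elements", [str(x) for x in topology.elements])
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        u.atoms.positions = frame.coordinates.astype(np.float32)
        u.dimensions = np.array([*frame.box, 90.0, 90.0, 90.0],
                                dtype=np.float32)
    return u


def _topology_from_elements(elements, group_map, resname="UNK",
                            group_tag=None):
    atoms = []
    for k, el in enumerate(elements):
        el = str(el)
        rn = {"O": "HOH", "H": "HOH"}.get(el.upper(), resname)
        tag = group_tag or _group_for_residue(rn, group_map)
        atoms.append(Atom(k, el, el, element_mass(el), rn, k, k, tag))
    return Topology(atoms)


# ---------------------------------------------------------------------------
# extended XYZ dialect
# ---------------------------------------------------------------------------

def _write_xyz_block(fh, elements, frame: Frame, data=None):
    coords = frame.coordinates if data is None else data
    fh.write(f"{len(coords)}\n")
    fh.write("box %.6f %.6f %.6f time %.6f\n" % (*frame.box, frame.time))
    for el, (x, y, z) in zip(elements, coords):
        fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz_frames(path, box_override=None):
    frames, elements = [], None
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FileFormatError(f"{path}:{i + 1}: expected atom count")
        if i + 1 >= len(lines):
            raise FileFormatError(f"{path}:{i + 1}: missing comment line")
        comment = lines[i + 1].split()
        box, time = None, 0.0
        for k, tok in enumerate(comment):
            if tok == "box" and k + 3 < len(comment) + 1:
                try:
                    box = [float(comment[k + 1]), float(comment[k + 2]),
                           float(comment[k + 3])]
                except (ValueError, IndexError):
                    raise FileFormatError(
                        f"{path}:{i + 2}: malformed box in comment line")
            if tok == "time":
                try:
                    time = float(comment[k + 1])
                except (ValueError, IndexError):
                    raise FileFormatError(
                        f"{path}:{i + 2}: malformed time in comment line")
        if box is None:
            if box_override is None:
                raise FileFormatError(
                    f"{path}:{i + 2}: comment line lacks 'box a b c'; pass box=")
            box = box_override
        if i + 2 + n > len(lines):
            warnings.warn(f"{path}: truncated final frame dropped")
            break
        els, coords = [], np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise FileFormatError(
                    f"{path}:{i + 3 + k}: expected 'element x y z'")
            els.append(parts[0])
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FileFormatError(
                    f"{path}:{i + 3 + k}: malformed coordinates")
        if elements is None:
            elements = els
        frames.append(Frame(time=time, box=box, coordinates=coords))
        i += 2 + n
    return frames, (elements or [])


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def read_trajectory(paths, topology: Topology, format=None, dt=None,
                    velocity_paths=None) -> Trajectory:
    """Read one or more frame files against an existing topology.

    ``dt`` (ps) overrides/provides frame spacing when files carry no times.
    ``velocity_paths`` is a parallel XYZ-multi stream read as velocities
    (Å/ps).
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    fmt = _infer_format(str(paths[0]), format)
    frames = []
    if fmt in ("xyz", "xyz-multi"):
        for p in paths:
            fr, _ = _read_xyz_frames(p)
            frames.extend(fr)
    elif fmt == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader
        for p in paths:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reader = DCDReader(p)
            if reader.n_atoms != topology.n_atoms:
                raise FileFormatError(
                    f"{p}: frame 0 has {reader.n_atoms} atoms, topology has "
                    f"{topology.n_atoms}")
            file_dt = dt if dt is not None else float(reader.ts.dt)
            for k, ts in enumerate(reader):
                dims = ts.dimensions
                box = dims[:3] if dims is not None and np.any(dims[:3] > 0) \
                    else [1.0, 1.0, 1.0]
                frames.append(Frame(time=k * file_dt,
                                    box=np.asarray(box, dtype=float),
                                    coordinates=ts.positions.astype(float)))
            reader.close()
    else:
        raise FileFormatError(f"unsupported trajectory format {fmt!r}")

    for k, fr in enumerate(frames):
        if fr.n_atoms != topology.n_atoms:
            raise FileFormatError(
                f"frame {k}: atom count {fr.n_atoms} != topology "
                f"{topology.n_atoms}")

    if dt is not None:
        frames = [Frame(time=k * dt, box=f.box, coordinates=f.coordinates,
                        velocities=f.velocities)
                  for k, f in enumerate(frames)]
    elif frames and len({f.time for f in frames}) != len(frames):
        frames = [Frame(time=float(k), box=f.box, coordinates=f.coordinates,
                        velocities=f.velocities)
                  for k, f in enumerate(frames)]

    if velocity_paths is not None:
        if isinstance(velocity_paths, (str, os.PathLike)):
            velocity_paths = [velocity_paths]
        vel_frames = []
        for p in velocity_paths:
            fr, _ = _read_xyz_frames(p, box_override=[1, 1, 1])
            vel_frames.extend(fr)
        if len(vel_frames) != len(frames):
            raise FileFormatError(
                f"velocity stream has {len(vel_frames)} frames, "
                f"coordinates have {len(frames)}")
        frames = [Frame(time=f.time, box=f.box, coordinates=f.coordinates,
                        velocities=vf.coordinates)
                  for f, vf in zip(frames, vel_frames)]
    return Trajectory(topology, frames)


def write_trajectory(path, traj: Trajectory, format=None,
                     velocity_path=None):
    """Write a trajectory as XYZ-multi or DCD; velocities optionally to a
    parallel XYZ-multi stream."""
    fmt = _infer_format(str(path), format)
    if fmt in ("xyz", "xyz-multi"):
        with open(path, "w") as fh:
            for fr in traj.frames:
                _write_xyz_block(fh, traj.topology.elements, fr)
    elif fmt == "dcd":
        import MDAnalysis as mda
        u = _mda_universe(traj.topology, traj.frames[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.coordinates.DCD.DCDWriter(
                    path, n_atoms=traj.topology.n_atoms,
                    dt=traj.dt or 1.0) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.coordinates.astype(np.float32)
                    u.dimensions = np.array([*fr.box, 90, 90, 90],
                                            dtype=np.float32)
                    w.write(u.atoms)
    else:
        raise FileFormatError(f"unsupported trajectory format {fmt!r}")
    if velocity_path is not None:
        if not traj.has_velocities():
            raise ValueError("trajectory has no velocities to write")
        with open(velocity_path, "w") as fh:
            for fr in traj.frames:
                _write_xyz_block(fh, traj.topology.elements, fr,
                                 data=fr.velocities)
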