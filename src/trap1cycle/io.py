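"""Readers and writers for the package's plain-text formats.

Traces, mixing tables and distance distributions travel as CSV; trajectories
as multi-model PDB (via biotite) or a timestamped XYZ variant; state graphs
and fit reports as JSON.

Trace CSV convention: two columns named ``time_<unit>`` and ``value_<kind>``
(e.g. ``time_min,value_rfu``); UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import io as _io
from typing import Optional

import numpy as np
import pandas as pd

from .deer_conformers import DistanceDistribution
from .kinetics import SIGNAL_KINDS, KineticTrace
from .mixing_model import MixTable
from .units import TIME_UNITS
from .water_dynamics import ROLE_SITE, ROLE_WATER, TrajectoryFrames


# ---------------------------------------------------------------- traces

def write_trace(trace: KineticTrace, path) -> None:
    df = pd.DataFrame(
        {f"time_{trace.time_unit}": trace.times, f"value_{trace.kind}": trace.values}
    )
    df.to_csv(path, index=False)


def read_trace(path, time_unit: Optional[str] = None, kind: Optional[str] = None,
               label: str = "") -> KineticTrace:
    """Read a trace CSV; unit and kind come from the header unless overridden."""
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c.startswith("time")), None)
    value_col = next((c for c in df.columns if c.startswith("value")), None)
    if time_col is None or value_col is None:
        raise ValueError("trace CSV needs 'time_<unit>' and 'value_<kind>' columns")
    if time_unit is None:
        suffix = time_col[5:] if time_col.startswith("time_") else ""
        time_unit = suffix if suffix in TIME_UNITS else "min"
    if kind is None:
        suffix = value_col[6:] if value_col.startswith("value_") else ""
        kind = suffix if suffix in SIGNAL_KINDS else "rfu"
    return KineticTrace(
        df[time_col].to_numpy(float), df[value_col].to_numpy(float),
        time_unit=time_unit, kind=kind, label=label,
    )


# ----------------------------------------------------------- mixing table

def write_mix_table(table: MixTable, path) -> None:
    df = pd.DataFrame({"f_wildtype": table.f_wildtype, "v_total": table.v_total})
    if table.sd is not None:
        df["sd"] = table.sd
    df.to_csv(path, index=False)


def read_mix_table(path) -> MixTable:
    df = pd.read_csv(path)
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    return MixTable(df["f_wildtype"].to_numpy(float), df["v_total"].to_numpy(float), sd=sd)


# ------------------------------------------------- distance distributions

def write_distance_distribution(dist: DistanceDistribution, path) -> None:
    pd.DataFrame({"r_angstrom": dist.r, "p": dist.p}).to_csv(path, index=False)


def read_distance_distribution(path, renormalize: bool = True) -> DistanceDistribution:
    df = pd.read_csv(path)
    r = df["r_angstrom"].to_numpy(float)
    p = df["p"].to_numpy(float)
    if renormalize:
        return DistanceDistribution.from_unnormalized(r, p)
    return DistanceDistribution(r, p)


# ------------------------------------------------------------ trajectories

#: how trajectory atom records map onto analysis roles
DEFAULT_ROLE_MAP = {
    "water_res_name": "HOH",
    "water_atom_name": "O",
    "site_res_name": "SIT",
    "site_chains": {"A": "buckled", "B": "straight"},
}


def write_multi_model_pdb(traj: TrajectoryFrames, path,
                          role_map: Optional[dict] = None) -> None:
    """Write frames as MODEL/ENDMDL records (water oxygens + site atoms)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    rm = {**DEFAULT_ROLE_MAP, **(role_map or {})}
    site_chain = {v: k for k, v in rm["site_chains"].items()}
    n_atoms = len(traj.atoms)
    arr = struc.AtomArrayStack(traj.n_frames, n_atoms)
    arr.coord[:] = traj.coords
    res_names, atom_names, chains, elements = [], [], [], []
    for _, row in traj.atoms.iterrows():
        if row["role"] == ROLE_WATER:
            res_names.append(rm["water_res_name"])
            atom_names.append(rm["water_atom_name"])
            chains.append("W")
            elements.append("O")
        elif row["role"] == ROLE_SITE:
            res_names.append(rm["site_res_name"])
            atom_names.append("P")
            chains.append(site_chain.get(row["site"], "A"))
            elements.append("P")
        else:
            res_names.append("UNK")
            atom_names.append("X")
            chains.append("X")
            elements.append("C")
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(atom_names)
    arr.chain_id = np.array(chains)
    arr.element = np.array(elements)
    arr.res_id = np.arange(1, n_atoms + 1)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_multi_model_pdb(path, frame_interval: float = 3.0,
                         role_map: Optional[dict] = None) -> TrajectoryFrames:
    """Read a MODEL/ENDMDL trajectory; PDB carries no times, so frame times
    are ``frame_interval`` (ns) apart."""
    from biotite.structure.io.pdb import PDBFile

    rm = {**DEFAULT_ROLE_MAP, **(role_map or {})}
    arr = PDBFile.read(str(path)).get_structure()
    roles, sites, ids = [], [], []
    for i in range(arr.array_length()):
        res, name, chain = arr.res_name[i], arr.atom_name[i], arr.chain_id[i]
        if res == rm["water_res_name"] and name == rm["water_atom_name"]:
            roles.append(ROLE_WATER)
            sites.append("")
        elif res == rm["site_res_name"]:
            roles.append(ROLE_SITE)
            sites.append(rm["site_chains"].get(chain, ""))
        else:
            roles.append("other")
            sites.append("")
        ids.append(f"{res}_{i}")
    atoms = pd.DataFrame({"id": ids, "role": roles, "site": sites})
    times = np.arange(arr.stack_depth()) * frame_interval
    return TrajectoryFrames(arr.coord, atoms, times)


#: XYZ symbols for the timestamped-XYZ variant
XYZ_SYMBOLS = {"OW": (ROLE_WATER, ""), "PA": (ROLE_SITE, "buckled"), "PB": (ROLE_SITE, "straight")}


def write_xyz(traj: TrajectoryFrames, path) -> None:
    """Timestamped XYZ: the comment line of each frame carries ``t= <ns>``."""
    sym_for = {}
    for _, row in traj.atoms.iterrows():
        if row["role"] == ROLE_WATER:
            sym_for[row["id"]] = "OW"
        elif row["role"] == ROLE_SITE:
            sym_for[row["id"]] = "PA" if row["site"] == "buckled" else "PB"
        else:
            sym_for[row["id"]] = "X"
    buf = _io.StringIO()
    ids = traj.atoms["id"].tolist()
    for f in range(traj.n_frames):
        buf.write(f"{len(ids)}\n")
        buf.write(f"t= {traj.times[f]:.6f}\n")
        for a, aid in enumerate(ids):
            x, y, z = traj.coords[f, a]
            buf.write(f"{sym_for[aid]} {x:.4f} {y:.4f} {z:.4f}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_xyz(path) -> TrajectoryFrames:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    frames, times = [], []
    symbols: Optional[list] = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        t = float(comment.split("t=")[1].split()[0]) if "t=" in comment else float(len(times))
        syms, xyz = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            syms.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if symbols is None:
            symbols = syms
        elif syms != symbols:
            raise ValueError("atom table differs between XYZ frames")
        frames.append(xyz)
        times.append(t)
        i += 2 + n
    roles, sites, ids = [], [], []
    for k, sym in enumerate(symbols or []):
        role, site = XYZ_SYMBOLS.get(sym, ("other", ""))
        roles.append(role)
        sites.append(site)
        ids.append(f"{sym}_{k}")
    atoms = pd.DataFrame({"id": ids, "role": roles, "site": sites})
    return TrajectoryFrames(np.asarray(frames, dtype=float), atoms, np.asarray(times, dtype=float))
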