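"""File formats: Cα-PDB structures, tab-delimited tables, plain-text config.

Conventions: UTF-8, tab-delimited tables with ``#`` comment headers that
must declare units (readers reject unitless files); lengths nm, forces pN,
times s.  PDB coordinates are Angstrom on disk and converted to nm on read.
Every writer stamps a config hash so a run can be reproduced bit-identically
from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .pulling import PullTrace

__all__ = [
    "read_pdb_calpha",
    "write_pdb_calpha",
    "read_trace",
    "write_trace",
    "read_config",
    "write_config",
    "config_hash",
    "read_environment",
    "write_environment",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_pdb_calpha(path, chain_id: str | None = None, model: int = 1):
    """Cα coordinates (nm) and one-letter sequence from a PDB file.

    Residues are taken in order of occurrence (insertion codes follow file
    order); of alternate locations the highest-occupancy one is kept.
    Raises when a residue has no Cα atom.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    if chain_id is not None:
        atoms = atoms[atoms.chain_id == chain_id]
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms found (chain {chain_id!r}) in {path}")
    coords, seq = [], []
    for residue in struc.residue_iter(atoms):
        ca = residue[residue.atom_name == "CA"]
        res_name = residue.res_name[0]
        res_id = residue.res_id[0]
        if ca.array_length() == 0:
            raise ValueError(f"residue {res_name} {res_id} has no CA atom")
        coords.append(ca.coord[0] / 10.0)  # Angstrom -> nm
        seq.append(_THREE_TO_ONE.get(res_name, "X"))
    return np.array(coords), "".join(seq)


def write_pdb_calpha(path, positions, sequence: str, chain_id: str = "A") -> None:
    """Write a Cα-only PDB (positions in nm, stored as Angstrom)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if len(sequence) != n:
        raise ValueError("sequence length does not match coordinates")
    atoms = struc.AtomArray(n)
    atoms.coord = positions * 10.0
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array([_ONE_TO_THREE.get(a, "GLY") for a in sequence])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def config_hash(config: dict) -> str:
    """Short stable hash of a (JSON-serialisable) configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


_TRACE_COLUMNS = ["time_s", "extension_nm", "force_pN", "cycle", "direction"]


def write_trace(path, trace: PullTrace, config: dict | None = None) -> None:
    """Write a force-extension trace as tab-delimited text with unit header."""
    df = trace.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tunnelfold force-extension trace\n")
        fh.write("# units: time_s=s extension_nm=nm force_pN=pN\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trace(path) -> PullTrace:
    """Read a tab-delimited trace; rejects files without a units header."""
    header = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                header.append(line)
            else:
                break
    if not any("units:" in h for h in header):
        raise ValueError(f"{path} lacks the mandatory '# units:' header line")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing columns {missing}")
    return PullTrace(
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        cycle=df["cycle"].to_numpy(),
        direction=df["direction"].to_numpy(dtype=object),
    )


def write_environment(path, environment, config: dict | None = None) -> None:
    """Environment beads as tab-delimited x y z radius charge (nm, e)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tunnelfold environment beads\n")
        fh.write("# units: x=nm y=nm z=nm radius=nm charge=e\n")
        fh.write(f"# anchor_index: {environment.anchor_index}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        fh.write("x\ty\tz\tradius\tcharge\n")
        for p, r, q in zip(environment.positions, environment.radii, environment.charges):
            fh.write(f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{r:.4f}\t{q:.2f}\n")


def read_environment(path):
    """Read environment beads written by :func:`write_environment`."""
    from .cg import RibosomeEnvironment

    anchor = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# anchor_index:"):
                anchor = int(line.split(":")[1])
            if not line.startswith("#"):
                break
    if anchor is None:
        raise ValueError(f"{path} lacks the '# anchor_index:' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    return RibosomeEnvironment(
        positions=df[["x", "y", "z"]].to_numpy(),
        radii=df["radius"].to_numpy(),
        charges=df["charge"].to_numpy(),
        anchor_index=anchor,
    )


def write_config(path, config: dict) -> None:
    """Plain-text ``key = value`` config with [section] headers."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tunnelfold config (hash {config_hash(config)})\n")
        for section, values in config.items():
            fh.write(f"[{section}]\n")
            for key, val in values.items():
                fh.write(f"{key} = {val}\n")
            fh.write("\n")


def read_config(path) -> dict:
    """Parse a ``key = value`` sectioned config; values are auto-typed."""
    out: dict[str, dict] = {}
    section = None
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            out[section] = {}
            continue
        if "=" not in line or section is None:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        val = val.strip()
        for cast in (int, float):
            try:
                val = cast(val)
                break
            except ValueError:
                continue
        else:
            if val in ("true", "True"):
                val = True
            elif val in ("false", "False"):
                val = False
        out[section][key.strip()] = val
    return out
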