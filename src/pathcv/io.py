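"""Conformation and trajectory I/O.

Bead systems are written as PDB (beads as CA atoms of sequential GLY
residues, one MODEL per frame) or XYZ (one frame per block); both are
read back through MDAnalysis.  Low-dimensional surface states are
padded to 3D with zero z (and zero y for 1D systems) so every path and
trajectory can round-trip through the same formats.  Tabular outputs
(strings, PMFs, clusters, networks, RMSF, driving) are plain TSV.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .errors import FileFormatError, SpecError

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "read_pdb",
    "read_conformations",
    "write_path_tsv",
    "pad_to_3d",
    "flatten_frames",
]


def pad_to_3d(states: np.ndarray) -> np.ndarray:
    """(n, d) flat states with d < 3 → (n, 1, 3) particle coordinates."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    d = states.shape[-1]
    if d % 3 == 0:
        return states.reshape(states.shape[0], d // 3, 3)
    out = np.zeros((states.shape[0], 1, 3))
    out[:, 0, :d] = states
    return out


def flatten_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    return frames.reshape(frames.shape[0], -1)


def _universe(n_atoms: int) -> "mda.Universe":
    u = mda.Universe.empty(n_atoms, n_residues=n_atoms,
                           atom_resindex=np.arange(n_atoms),
                           residue_segindex=np.zeros(n_atoms, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", ["CA"] * n_atoms)
    u.add_TopologyAttr("resnames", ["GLY"] * n_atoms)
    u.add_TopologyAttr("resids", np.arange(1, n_atoms + 1))
    u.add_TopologyAttr("elements", ["C"] * n_atoms)
    return u


def write_xyz(path, frames, precision: int = 12) -> None:
    """Write frames (n_frames, n_particles, 3) as multi-frame XYZ."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    u = _universe(frames.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.XYZ.XYZWriter(str(path), n_atoms=frames.shape[1],
                                           precision=precision) as w:
            for f in frames:
                u.atoms.positions = f
                w.write(u.atoms)


def read_xyz(path) -> np.ndarray:
    """Read a (possibly multi-frame) XYZ file to (n_frames, n_particles, 3)."""
    return _read(path, "XYZ")


def write_pdb(path, frames) -> None:
    """Write frames as a multi-model PDB with beads as CA atoms."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    u = _universe(frames.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=frames.shape[1]) as w:
            for f in frames:
                u.atoms.positions = f
                w.write(u.atoms)


def read_pdb(path) -> np.ndarray:
    return _read(path, "PDB")


def _read(path, fmt: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileFormatError(f"{path}: no such file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
            frames = np.array([u.atoms.positions.astype(float).copy()
                               for _ in u.trajectory])
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FileFormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if frames.size == 0:
        raise FileFormatError(f"{path}: no frames found")
    return frames


def read_conformations(path, fmt: str | None = None) -> np.ndarray:
    """Read a pool of conformations from PDB or XYZ (by extension if
    ``fmt`` is not given); coordinates in Å, frame order preserved."""
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = {"": "PDB", ".pdb": "PDB", ".xyz": "XYZ"}.get(ext)
        if fmt is None:
            raise SpecError(f"cannot infer format from extension {ext!r}")
    fmt = fmt.upper()
    if fmt not in ("PDB", "XYZ"):
        raise SpecError(f"unsupported format {fmt!r}; expected PDB or XYZ")
    return _read(path, fmt)


def write_path_tsv(path, images, energies=None) -> None:
    """Sidecar table for a path: image index, arc-length parameter, energy."""
    from .zts import arc_lengths

    images = np.asarray(images, dtype=float)
    s = arc_lengths(images)
    df = pd.DataFrame({
        "image": np.arange(len(images)),
        "alpha": s / s[-1] if s[-1] > 0 else s,
    })
    if energies is not None:
        df["energy"] = np.asarray(energies, dtype=float)
    df.to_csv(path, sep="\t", index=False)
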