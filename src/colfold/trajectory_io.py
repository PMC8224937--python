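"""Trajectory and scalar-series I/O in plain interchange formats.

Multi-model PDB is the trajectory interchange format; per-frame scalar
series and per-triplet matrices travel as CSV with ``frame_index`` and
``time_ps`` leading columns. Coordinates are Å, times ps throughout
(nanoseconds appear only in reports).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .helix_model import StructureModel

__all__ = [
    "Trajectory",
    "ScalarSeries",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_structure_pdb",
    "write_structure_pdb",
    "write_series_csv",
    "read_series_csv",
    "load_config",
]


class TrajectoryFormatError(ValueError):
    """Raised for malformed multi-model files or CSV series."""


@dataclass
class Trajectory:
    """Frames sharing one topology, uniformly spaced in time.

    ``topology`` carries the atom table; ``coords`` has shape
    (n_frames, n_atoms, 3) in Å; ``dt`` is the frame spacing in ps.
    """

    topology: StructureModel
    coords: np.ndarray
    dt: float = 50.0
    t0: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class ScalarSeries:
    """Per-frame real values with a units tag."""

    values: np.ndarray
    dt: float = 50.0
    t0: float = 0.0
    units: str = ""
    name: str = "value"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_ELEMENT_GUESS = {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H"}


def _model_to_atom_array(model: StructureModel) -> struc.AtomArray:
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = model.chain_ids
    arr.res_id = model.res_indices
    arr.res_name = model.res_names
    arr.atom_name = model.atom_names
    arr.element = model.elements
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = model.coords
    return arr


def _atom_array_to_model(arr: struc.AtomArray) -> StructureModel:
    elements = np.array(
        [e if e else _ELEMENT_GUESS.get(a[:1], "C") for e, a in zip(arr.element, arr.atom_name)]
    )
    return StructureModel(
        np.asarray(arr.chain_id),
        np.asarray(arr.res_id),
        np.asarray(arr.res_name),
        np.asarray(arr.atom_name),
        elements,
        np.asarray(arr.coord, dtype=float),
    )


def _validate_model_blocks(path) -> None:
    """Pre-scan MODEL/ENDMDL blocks so atom-count mismatches are reported
    with the offending model index (the underlying reader's stacking error
    is opaque)."""
    counts = []
    current = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = 0
                    counts.append(None)  # single implicit model
                current += 1
            elif rec == "ENDMDL":
                counts.append(current if current is not None else 0)
                current = None
    if current is not None and (not counts or counts[-1] is not None):
        counts.append(current)
    counts = [c for c in counts if c is not None]
    if not counts:
        raise TrajectoryFormatError(f"{path}: no ATOM records found")
    first = counts[0]
    for i, c in enumerate(counts, start=1):
        if c != first:
            raise TrajectoryFormatError(
                f"{path}: model {i} has {c} atoms, expected {first} (model 1)"
            )


def read_multimodel_pdb(path, dt: float = 50.0, t0: float = 0.0) -> Trajectory:
    """Read a multi-model PDB file as a Trajectory (frames in file order).

    The frame spacing is not stored in PDB; pass ``dt`` (ps, default 50).
    """
    _validate_model_blocks(path)
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    topo = _atom_array_to_model(stack[0])
    return Trajectory(topo, np.asarray(stack.coord, dtype=float), dt=dt, t0=t0)


def read_structure_pdb(path, max_chains: int = 3, max_residues: int | None = None) -> StructureModel:
    """Read a single-model PDB as a StructureModel reference.

    Only the first ``max_chains`` chains (and optionally the first
    ``max_residues`` residues of each) are kept, so an external reference
    structure can stand in for the built helix.
    """
    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    arr = arr[~arr.hetero]
    chains = []
    for c in arr.chain_id:
        if c not in chains:
            chains.append(c)
    keep_chains = chains[:max_chains]
    arr = arr[np.isin(arr.chain_id, keep_chains)]
    if max_residues is not None:
        keep = np.zeros(arr.array_length(), dtype=bool)
        for c in keep_chains:
            m = arr.chain_id == c
            ids = np.unique(arr.res_id[m])[:max_residues]
            keep |= m & np.isin(arr.res_id, ids)
        arr = arr[keep]
    return _atom_array_to_model(arr)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    arr = _model_to_atom_array(traj.topology)
    coords = traj.coords
    stack = struc.AtomArrayStack(coords.shape[0], arr.array_length())
    for name in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(name, arr.get_annotation(name))
    stack.coord = coords
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_structure_pdb(model: StructureModel, path) -> None:
    """Write a single StructureModel as a one-model PDB file."""
    f = pdb.PDBFile()
    f.set_structure(_model_to_atom_array(model))
    f.write(str(path))


# ---------------------------------------------------------------------------
# CSV series / matrices
# ---------------------------------------------------------------------------


def write_series_csv(data, path, dt: float = 50.0, t0: float = 0.0, labels=None) -> None:
    """Write a ScalarSeries or a (frames × columns) matrix as CSV.

    Layout: header row; columns ``frame_index``, ``time_ps``, then either
    the series name or one column per matrix column (default labels
    ``triplet_1..triplet_L`` for profile matrices).
    """
    if isinstance(data, ScalarSeries):
        values = data.values[:, None]
        labels = [data.name or "value"]
        dt, t0 = data.dt, data.t0
    else:
        values = np.asarray(data, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if labels is None:
            labels = [f"triplet_{i + 1}" for i in range(values.shape[1])]
    n = values.shape[0]
    frame = pd.DataFrame(
        {"frame_index": np.arange(n), "time_ps": t0 + dt * np.arange(n)}
    )
    for j, lab in enumerate(labels):
        frame[lab] = values[:, j]
    frame.to_csv(path, index=False)


def read_series_csv(path):
    """Read a series/matrix CSV written by :func:`write_series_csv`.

    Returns ``(values, times, labels)``; a single value column comes back
    as a ScalarSeries.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        # pandas reports the offending line in its message
        raise TrajectoryFormatError(f"{path}: malformed CSV: {exc}") from None
    required = ("frame_index", "time_ps")
    for col in required:
        if col not in frame.columns:
            raise TrajectoryFormatError(f"{path}: missing column {col!r} (line 1)")
    times = frame["time_ps"].to_numpy(dtype=float)
    labels = [c for c in frame.columns if c not in required]
    numeric = frame[labels].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise TrajectoryFormatError(f"{path}: non-numeric/missing value at line {row + 2}")
    if len(times) > 1:
        dt = float(times[1] - times[0])
    else:
        dt = 50.0
    t0 = float(times[0]) if len(times) else 0.0
    values = numeric.to_numpy(dtype=float)
    if values.shape[1] == 1:
        return ScalarSeries(values[:, 0], dt=dt, t0=t0, name=labels[0]), times, labels
    return values, times, labels


def load_config(path) -> dict:
    """Load a plain-text configuration file (YAML key-value sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
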