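"""Physicochemical index table and per-property cone geometry.

Each physicochemical property induces an ordering of the 20 amino acids from
the lowest to the highest value. The ranked residues are placed on the unit
circle at the base of a right circular cone of height 1:

    Phi(A_i) = (cos(2*pi*i/20), sin(2*pi*i/20), 1),   i = 1..20 (the rank),

and every ordered residue pair is attached near that circle as

    Phi(A_i A_j) = Phi(A_i) + Phi(A_j) / 4,

so all 400 pair points sit at height z = 1.25. The geometry depends on the
property only through the induced ordering; properties with identical values
for all 20 residues are degenerate and rejected.

The bundled default table (``data/physchem_indices_synthetic.tsv``) holds 158
properties: five well-known published scales plus seeded synthetic rows. It
is a stand-in — the original 158-index selection used for this task was never
published — and any user table with >= 1 non-degenerate property is accepted;
all downstream feature dimensions scale as P + 420.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS

__all__ = [
    "PhysChemIndexTable",
    "ConeGeometry",
    "load_default_table",
    "load_table",
    "rank_amino_acids",
    "vertex_points",
    "pair_points",
    "cone_geometry",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def rank_amino_acids(values: np.ndarray | dict[str, float]) -> np.ndarray:
    """Order the 20 amino acids by property value, lowest first.

    ``values`` is either a dict keyed by one-letter code or an array in
    alphabetical residue order. Returns an integer array ``order`` where
    ``order[i]`` is the alphabetical index of the residue holding rank i+1.
    Ties are broken alphabetically; a property with all 20 values identical
    raises ``ValueError`` (degenerate index).
    """
    if isinstance(values, dict):
        arr = np.array([float(values[aa]) for aa in AMINO_ACIDS])
    else:
        arr = np.asarray(values, dtype=float)
    if arr.shape != (20,):
        raise ValueError(f"expected 20 values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite property values")
    if np.all(arr == arr[0]):
        raise ValueError("degenerate index: all 20 values identical")
    # stable sort on values; equal values keep alphabetical input order
    return np.argsort(arr, kind="stable")


def vertex_points(ordering: np.ndarray) -> np.ndarray:
    """20 x 3 array of cone-base points, indexed by alphabetical residue index.

    The residue of rank i (1-based) sits at (cos(2*pi*i/20), sin(2*pi*i/20), 1);
    in particular rank 20 coincides with angle 0, i.e. the point (1, 0, 1).
    """
    ordering = np.asarray(ordering)
    ranks = np.empty(20, dtype=float)
    ranks[ordering] = np.arange(1, 21)
    theta = 2.0 * np.pi * ranks / 20.0
    return np.column_stack([np.cos(theta), np.sin(theta), np.ones(20)])


def pair_points(vertices: np.ndarray) -> np.ndarray:
    """20 x 20 x 3 array: point for the ordered pair (a, b) is
    ``vertices[a] + vertices[b] / 4`` (every pair point has z = 1.25)."""
    v = np.asarray(vertices, dtype=float)
    return v[:, None, :] + 0.25 * v[None, :, :]


@dataclass(frozen=True)
class ConeGeometry:
    """Cone geometry induced by one property ordering.

    ``vertex`` and ``pair`` are indexed by alphabetical residue index (A=0 …
    Y=19), not by rank, so sequence lookups need no indirection.
    """

    ordering: np.ndarray  # rank -> alphabetical residue index
    vertex: np.ndarray  # (20, 3)
    pair: np.ndarray  # (20, 20, 3)

    def rank_of(self, aa: str) -> int:
        """1-based rank of residue ``aa`` under this property."""
        return int(np.where(self.ordering == _AA_INDEX[aa])[0][0]) + 1


def cone_geometry(values: np.ndarray | dict[str, float]) -> ConeGeometry:
    """Build the full cone geometry for one property."""
    ordering = rank_amino_acids(values)
    v = vertex_points(ordering)
    return ConeGeometry(ordering=ordering, vertex=v, pair=pair_points(v))


class PhysChemIndexTable:
    """A matrix of P physicochemical properties x 20 amino-acid values.

    Degenerate rows (all 20 values identical) are removed at load time; the
    effective property count is ``len(table)`` and is reported by ``repr``.
    """

    def __init__(self, names: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValueError(f"values must be (P, 20), got {values.shape}")
        if len(names) != values.shape[0]:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite values in index table")
        keep = [i for i in range(values.shape[0]) if not np.all(values[i] == values[i, 0])]
        self.n_dropped = values.shape[0] - len(keep)
        self.names = [names[i] for i in keep]
        self.values = values[keep]
        if len(self.names) == 0:
            raise ValueError("index table has no non-degenerate properties")
        self._geometries: list[ConeGeometry] | None = None

    def __len__(self) -> int:
        return len(self.names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhysChemIndexTable(P={len(self)}, dropped={self.n_dropped})"

    def subset(self, k: int) -> "PhysChemIndexTable":
        """First ``k`` properties (useful for quick runs and examples)."""
        return PhysChemIndexTable(self.names[:k], self.values[:k])

    @property
    def geometries(self) -> list[ConeGeometry]:
        if self._geometries is None:
            self._geometries = [cone_geometry(row) for row in self.values]
        return self._geometries

    def stacked_geometry(self) -> tuple[np.ndarray, np.ndarray]:
        """(P, 20, 3) vertex and (P, 20, 20, 3) pair arrays for fast featurizing."""
        geoms = self.geometries
        return (
            np.stack([g.vertex for g in geoms]),
            np.stack([g.pair for g in geoms]),
        )


def load_table(path: str | Path) -> PhysChemIndexTable:
    """Load a tab-separated index table: header of amino-acid codes, one
    property per row with the name in column 1; ``#`` lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    name_col = df.columns[0]
    cols = list(df.columns[1:])
    missing = [aa for aa in AMINO_ACIDS if aa not in cols]
    if missing:
        raise ValueError(f"{path}: missing amino-acid columns: {missing}")
    values = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    return PhysChemIndexTable(df[name_col].astype(str).tolist(), values)


def load_default_table() -> PhysChemIndexTable:
    """The bundled 158-property table (synthetic stand-in, documented in
    the module docstring)."""
    ref = resources.files("fegsnet.data").joinpath("physchem_indices_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_table(path)
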