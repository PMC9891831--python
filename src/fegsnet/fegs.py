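"""Graphical + statistical protein features (FEGS-style).

For each physicochemical property a protein of length N is drawn as a 3D
curve: starting at the origin, the first step adds the cone vertex point of
the first residue and every later step i adds the pair point of the dipeptide
s_{i-1} s_i, giving points P_0 .. P_N with one new point per residue.

The curve (points P_1..P_N; the synthetic origin is excluded) is summarised
by the symmetric N x N distance-quotient matrix

    M_ij = ||P_i - P_j|| / (along-curve path length from P_i to P_j),

the classic Euclidean-over-graph-distance construction: entries lie in
(0, 1], adjacent points give exactly 1, and the diagonal is zero. The scalar
feature per property is the leading eigenvalue of M divided by N, which
removes the gross length dependence so short and long proteins are
comparable. P such eigen-features are concatenated with the 20 amino-acid
composition (AAC) frequencies and the 400 dipeptide composition (DPC)
frequencies into a (P + 420)-dimensional vector — 578 at the default
158-property table.

Memory is O(N^2) per curve; sequences of a few thousand residues are fine,
very long ones are not the target of this representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import squareform, pdist

from .physchem import ConeGeometry, PhysChemIndexTable, load_default_table
from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence

__all__ = [
    "Curve3D",
    "FeatureLayout",
    "encode_sequence",
    "build_curve",
    "distance_quotient_matrix",
    "eigen_feature",
    "aac",
    "dpc",
    "fegs_vector",
    "featurize_dataset",
    "write_feature_matrix",
    "read_feature_matrix",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


def encode_sequence(seq: ProteinSequence | str) -> np.ndarray:
    """Map residues to alphabetical indices 0..19; unknown residue is an error."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    try:
        return np.array([_AA_INDEX[ch] for ch in residues], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - unreachable after cleaning
        raise ValueError(f"residue {exc.args[0]!r} outside the 20-letter alphabet")


@dataclass(frozen=True)
class Curve3D:
    """Ordered curve points P_0..P_N (shape (N+1, 3)); P_0 is the origin."""

    points: np.ndarray

    def __len__(self) -> int:
        return self.points.shape[0]


def build_curve(seq: ProteinSequence | str, geometry: ConeGeometry) -> Curve3D:
    """Draw the 3D curve of ``seq`` under one property's cone geometry.

    P_0 = (0,0,0); P_1 = P_0 + Phi(s_1) (vertex point of the first residue);
    P_i = P_{i-1} + Phi(s_{i-1} s_i) for i >= 2 (pair point of the trailing
    dipeptide). Requires length >= 2.
    """
    s = encode_sequence(seq)
    n = s.size
    if n < 2:
        raise ValueError("curve construction needs at least 2 residues")
    steps = np.empty((n, 3))
    steps[0] = geometry.vertex[s[0]]
    steps[1:] = geometry.pair[s[:-1], s[1:]]
    points = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Curve3D(points=points)


def distance_quotient_matrix(curve: Curve3D) -> np.ndarray:
    """Symmetric L x L quotient matrix over curve points P_1..P_L.

    Off-diagonal: straight-line distance divided by the summed lengths of the
    curve edges between the two points; diagonal zero. Since the straight
    line is never longer than the path, entries lie in (0, 1].
    """
    pts = np.asarray(curve.points, dtype=float)[1:]
    L = pts.shape[0]
    if L < 2:
        raise ValueError("need at least 2 residue points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite curve coordinates")
    euclid = squareform(pdist(pts))
    edge = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(edge)])
    path = np.abs(cum[:, None] - cum[None, :])
    with np.errstate(invalid="ignore"):
        M = np.where(path > 0, euclid / np.where(path > 0, path, 1.0), 0.0)
    np.fill_diagonal(M, 0.0)
    return M


def eigen_feature(M: np.ndarray, L: int | None = None) -> float:
    """Leading eigenvalue of the symmetric nonnegative matrix ``M``, divided
    by ``L`` (defaults to the matrix size)."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"M must be square, got {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite entries in M")
    n = M.shape[0]
    if L is None:
        L = n
    if n <= 32:
        lam = float(np.linalg.eigvalsh(M)[-1])
    else:
        # Lanczos for the largest algebraic eigenvalue; for a nonnegative
        # symmetric matrix this is the spectral radius (Perron-Frobenius).
        lam = float(eigsh(M, k=1, which="LA", return_eigenvectors=False)[0])
    return lam / float(L)


def aac(seq: ProteinSequence | str) -> np.ndarray:
    """20 amino-acid frequencies in fixed alphabetical order; sums to 1."""
    s = encode_sequence(seq)
    if s.size == 0:
        raise ValueError("empty sequence")
    return np.bincount(s, minlength=20) / s.size


def dpc(seq: ProteinSequence | str) -> np.ndarray:
    """400 ordered-dipeptide frequencies (AA, AC, ..., YY); sums to 1."""
    s = encode_sequence(seq)
    if s.size < 2:
        raise ValueError("dipeptide composition needs at least 2 residues")
    codes = s[:-1] * 20 + s[1:]
    return np.bincount(codes, minlength=400) / (s.size - 1)


@dataclass(frozen=True)
class FeatureLayout:
    """Column names of a feature matrix, in storage order."""

    descriptor: str
    columns: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.columns)


def fegs_layout(table: PhysChemIndexTable) -> FeatureLayout:
    cols = (
        [f"lambda_{name}" for name in table.names]
        + [f"AAC_{a}" for a in AMINO_ACIDS]
        + [f"DPC_{d}" for d in DIPEPTIDES]
    )
    return FeatureLayout(descriptor="fegs", columns=tuple(cols))


def _eigen_block(seq_codes: np.ndarray, vertex_all: np.ndarray, pair_all: np.ndarray) -> np.ndarray:
    """Eigen-features for all P properties of one encoded sequence.

    ``vertex_all`` is (P, 20, 3) and ``pair_all`` (P, 20, 20, 3); the P curves
    are built in one vectorised pass, then each quotient matrix is solved for
    its leading eigenvalue.
    """
    n = seq_codes.size
    P = vertex_all.shape[0]
    steps = np.empty((P, n, 3))
    steps[:, 0, :] = vertex_all[:, seq_codes[0], :]
    steps[:, 1:, :] = pair_all[:, seq_codes[:-1], seq_codes[1:], :]
    curves = np.cumsum(steps, axis=1)  # (P, n, 3): points P_1..P_n
    edge = np.linalg.norm(np.diff(curves, axis=1), axis=2)  # (P, n-1)
    cum = np.concatenate([np.zeros((P, 1)), np.cumsum(edge, axis=1)], axis=1)
    path = np.abs(cum[:, :, None] - cum[:, None, :])  # (P, n, n)
    out = np.empty(P)
    for p in range(P):
        sq = np.einsum("id,id->i", curves[p], curves[p])
        euclid2 = sq[:, None] + sq[None, :] - 2.0 * (curves[p] @ curves[p].T)
        np.maximum(euclid2, 0.0, out=euclid2)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.sqrt(euclid2) / path[p]
        np.fill_diagonal(M, 0.0)
        out[p] = eigen_feature(M, n)
    return out


def fegs_vector(
    seq: ProteinSequence | str, table: PhysChemIndexTable | None = None
) -> np.ndarray:
    """Full (P + 420)-dimensional feature vector of one cleaned sequence."""
    if table is None:
        table = load_default_table()
    s = encode_sequence(seq)
    if s.size < 2:
        raise ValueError("FEGS featurization needs at least 2 residues")
    vertex_all, pair_all = table.stacked_geometry()
    return np.concatenate([_eigen_block(s, vertex_all, pair_all), aac(seq), dpc(seq)])


def featurize_dataset(
    dataset: LabeledDataset | list[ProteinSequence],
    table: PhysChemIndexTable | None = None,
) -> tuple[np.ndarray, FeatureLayout]:
    """Feature matrix (n x (P+420)) with rows in dataset order."""
    if table is None:
        table = load_default_table()
    sequences = dataset.sequences if isinstance(dataset, LabeledDataset) else dataset
    layout = fegs_layout(table)
    X = np.empty((len(sequences), len(layout)))
    vertex_all, pair_all = table.stacked_geometry()
    for i, seq in enumerate(sequences):
        try:
            s = encode_sequence(seq)
            if s.size < 2:
                raise ValueError("fewer than 2 residues")
            X[i] = np.concatenate(
                [_eigen_block(s, vertex_all, pair_all), aac(seq), dpc(seq)]
            )
        except ValueError as exc:
            raise ValueError(f"sequence {seq.id!r}: {exc}") from exc
    return X, layout


def write_feature_matrix(
    path, ids: list[str], X: np.ndarray, layout: FeatureLayout
) -> None:
    """Tab-separated matrix with ``#`` layout comment lines and a header row."""
    with open(path, "w") as fh:
        fh.write(f"# descriptor: {layout.descriptor}\n")
        fh.write(f"# n_features: {len(layout)}\n")
        fh.write("id\t" + "\t".join(layout.columns) + "\n")
        for name, row in zip(ids, X):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_feature_matrix(path) -> tuple[list[str], np.ndarray, FeatureLayout]:
    descriptor = "unknown"
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# descriptor:"):
                    descriptor = line.split(":", 1)[1].strip()
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            ids.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    if header is None:
        raise ValueError(f"{path}: no header row")
    X = np.vstack(rows) if rows else np.empty((0, len(header)))
    return ids, X, FeatureLayout(descriptor=descriptor, columns=tuple(header))
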