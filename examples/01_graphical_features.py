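"""Featurize a couple of protein sequences with the graphical descriptor.

Builds the default 158-property cone geometry, draws the per-property 3D
curves for two short sequences and prints the resulting feature dimensions
plus a few values. The first block of the vector holds one normalized
leading eigenvalue per property (curve shape), followed by the 20 amino-acid
frequencies and the 400 dipeptide frequencies.
"""

import numpy as np

from fegsnet import fegs_vector, load_default_table
from fegsnet.fegs import build_curve, distance_quotient_matrix

table = load_default_table()
print(f"index table: {len(table)} properties")

seq = "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQT"
vec = fegs_vector(seq, table)
print(f"sequence length {len(seq)} -> feature vector of {vec.shape[0]} dims")
print(f"  eigen block (first 3 of {len(table)}): {np.round(vec[:3], 4)}")
print(f"  AAC block sums to {vec[len(table):len(table) + 20].sum():.3f}")
print(f"  DPC block sums to {vec[len(table) + 20:].sum():.3f}")

# peek at the geometry behind the first property
geometry = table.geometries[0]
curve = build_curve(seq, geometry)
M = distance_quotient_matrix(curve)
print(f"curve: {curve.points.shape[0]} points (N+1); quotient matrix {M.shape},"
      f" off-diagonal range [{M[M > 0].min():.3f}, {M.max():.3f}]")
# Entries near 1 mean the curve runs straight between those residues;
# small entries mean it folds back on itself.
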