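"""Amphiphilic pseudo-amino acid composition (Amp-PseAAC / APAAC).

The descriptor augments the 20 normalized residue frequencies with 2*lambda
sequence-order correlation factors computed from standardized hydrophobicity
(H1) and hydrophilicity (H2) scales:

    tau_{2k-1} = (1 / (N - k)) * sum_i H1(s_i) * H1(s_{i+k})
    tau_{2k}   = (1 / (N - k)) * sum_i H2(s_i) * H2(s_{i+k}),  k = 1..lambda

and the final (20 + 2*lambda)-vector is

    x_u = f_u / (1 + w * T)            for u = 1..20   (f = AAC frequencies)
    x_{20+j} = w * tau_j / (1 + w * T) for j = 1..2*lambda,  T = sum_j tau_j.

The vector always sums to 1; the tail entries can be negative because the
standardized scales are signed. Defaults lambda = 5 and w = 0.05 are the
classic pseudo-composition settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fegs import FeatureLayout, encode_sequence
from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence

__all__ = ["ApaacParams", "apaac", "apaac_layout", "featurize_dataset_apaac"]

# Tanford-style hydrophobicity and Hopp-Woods hydrophilicity, the two scales
# conventionally used by amphiphilic pseudo-composition; alphabetical order.
_H1_RAW = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_H2_RAW = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}


def _standardize(raw: dict[str, float]) -> np.ndarray:
    v = np.array([raw[a] for a in AMINO_ACIDS], dtype=float)
    return (v - v.mean()) / np.sqrt(((v - v.mean()) ** 2).mean())


H1 = _standardize(_H1_RAW)
H2 = _standardize(_H2_RAW)


@dataclass(frozen=True)
class ApaacParams:
    """lambda_tiers: correlation depth (>= 1); weight: tier weight (> 0)."""

    lambda_tiers: int = 5
    weight: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_tiers < 1:
            raise ValueError("lambda_tiers must be >= 1")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")

    @property
    def dimension(self) -> int:
        return 20 + 2 * self.lambda_tiers


def apaac(seq: ProteinSequence | str, params: ApaacParams | None = None) -> np.ndarray:
    """(20 + 2*lambda)-dimensional amphiphilic pseudo-composition vector."""
    if params is None:
        params = ApaacParams()
    s = encode_sequence(seq)
    n = s.size
    lam = params.lambda_tiers
    if n <= lam:
        name = seq.id if isinstance(seq, ProteinSequence) else "<sequence>"
        raise ValueError(
            f"sequence {name!r} has length {n} <= lambda_tiers={lam};"
            " shorten lambda or drop the sequence"
        )
    freqs = np.bincount(s, minlength=20) / n
    h1, h2 = H1[s], H2[s]
    tau = np.empty(2 * lam)
    for k in range(1, lam + 1):
        tau[2 * k - 2] = np.dot(h1[:-k], h1[k:]) / (n - k)
        tau[2 * k - 1] = np.dot(h2[:-k], h2[k:]) / (n - k)
    denom = 1.0 + params.weight * tau.sum()
    return np.concatenate([freqs, params.weight * tau]) / denom


def apaac_layout(params: ApaacParams | None = None) -> FeatureLayout:
    if params is None:
        params = ApaacParams()
    cols = [f"APAAC_{a}" for a in AMINO_ACIDS] + [
        f"tau_{k}_{scale}"
        for k in range(1, params.lambda_tiers + 1)
        for scale in ("hydrophobicity", "hydrophilicity")
    ]
    return FeatureLayout(descriptor="apaac", columns=tuple(cols))


def featurize_dataset_apaac(
    dataset: LabeledDataset | list[ProteinSequence],
    params: ApaacParams | None = None,
) -> tuple[np.ndarray, FeatureLayout]:
    if params is None:
        params = ApaacParams()
    sequences = dataset.sequences if isinstance(dataset, LabeledDataset) else dataset
    layout = apaac_layout(params)
    X = np.empty((len(sequences), len(layout)))
    for i, seq in enumerate(sequences):
        X[i] = apaac(seq, params)
    return X, layout
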