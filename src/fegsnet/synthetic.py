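"""Two-class synthetic protein sequence generator.

Sequences are drawn from a first-order Markov chain over the 20 amino acids
whose stationary background matches typical proteome composition. The
negative class uses the background chain; the positive class's transition
matrix is mixed toward a fixed set of "signature" dipeptides with weight
``effect``:

    T_pos[i, :] = (1 - effect) * T_bg[i, :] + effect * B[i, :]

where B spreads mass uniformly over the signature pairs starting at residue
i (rows without a signature pair keep the background law). ``effect = 0``
makes the two classes identically distributed; larger values strengthen the
dipeptide-order signal that DPC and the graphical curve features can see but
plain composition largely cannot. Lengths are uniform on ``length_range``
(default 50-400 residues, the scale of immunoglobulin-domain proteins);
everything is reproducible from the seed.

This generator emulates compositional/dipeptide class bias only — no
homology, domain architecture or real immunoglobulin biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import AMINO_ACIDS, LabeledDataset, ProteinSequence

__all__ = ["GeneratorConfig", "generate_dataset", "positive_transition_matrix", "background_transition_matrix"]

# Approximate background amino-acid frequencies of a large protein database.
_BACKGROUND = np.array(
    [
        0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0228, 0.0593,
        0.0581, 0.0965, 0.0241, 0.0406, 0.0472, 0.0394, 0.0553, 0.0660,
        0.0535, 0.0687, 0.0110, 0.0292,
    ]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

# Fixed signature dipeptides (40 ordered pairs), chosen once with a frozen
# seed so every GeneratorConfig shares the same positive-class signal.
_SIGNATURE_RNG = np.random.default_rng(414)
SIGNATURE_PAIRS = np.sort(_SIGNATURE_RNG.choice(400, size=40, replace=False))


@dataclass(frozen=True)
class GeneratorConfig:
    """n_pos/n_neg: class sizes; length_range: residue-count bounds (min >= 10);
    effect: class-separation strength in [0, 1]; seed: RNG seed."""

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (50, 400)
    effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}; need 10 <= min <= max")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be nonnegative")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be in [0, 1]")


def background_transition_matrix() -> np.ndarray:
    """20 x 20 background chain: every row is the background composition
    (i.e. an i.i.d. chain, the effect-0 law of both classes)."""
    return np.tile(_BACKGROUND, (20, 1))


def positive_transition_matrix(effect: float) -> np.ndarray:
    """Background chain mixed toward the signature dipeptides with weight
    ``effect``; rows remain probability distributions."""
    T = background_transition_matrix().copy()
    boost = np.zeros((20, 20))
    first, second = SIGNATURE_PAIRS // 20, SIGNATURE_PAIRS % 20
    for i, j in zip(first, second):
        boost[i, j] += 1.0
    row_sums = boost.sum(axis=1)
    has_sig = row_sums > 0
    boost[has_sig] /= row_sums[has_sig, None]
    T[has_sig] = (1.0 - effect) * T[has_sig] + effect * boost[has_sig]
    return T


def _sample_chain(rng: np.random.Generator, T_cum: np.ndarray, init_cum: np.ndarray, length: int) -> str:
    u = rng.random(length)
    out = np.empty(length, dtype=np.intp)
    out[0] = np.searchsorted(init_cum, u[0], side="right")
    for i in range(1, length):
        out[i] = np.searchsorted(T_cum[out[i - 1]], u[i], side="right")
    return "".join(AMINO_ACIDS[k] for k in out)


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Draw the two-class dataset; positives first, then negatives."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    init_cum = np.cumsum(_BACKGROUND)
    T_pos_cum = np.cumsum(positive_transition_matrix(config.effect), axis=1)
    T_neg_cum = np.cumsum(background_transition_matrix(), axis=1)
    sequences: list[ProteinSequence] = []
    labels: list[int] = []
    for label, count, T_cum, prefix in (
        (1, config.n_pos, T_pos_cum, "pos"),
        (0, config.n_neg, T_neg_cum, "neg"),
    ):
        lengths = rng.integers(lo, hi + 1, size=count)
        for idx in range(count):
            residues = _sample_chain(rng, T_cum, init_cum, int(lengths[idx]))
            sequences.append(ProteinSequence(f"{prefix}_{idx + 1:05d}", residues))
            labels.append(label)
    return LabeledDataset(sequences, labels)
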