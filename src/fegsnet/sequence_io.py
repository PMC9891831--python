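"""FASTA input/output, sequence cleaning and label handling.

Sequences are cleaned to the 20-letter amino-acid alphabet by removing the
ambiguous codes B, J, O, X, U and Z; cleaned sequences shorter than two
residues are dropped (with a warning) because the dipeptide and curve
descriptors are undefined on them.

Redundancy reduction (CD-HIT-style clustering) is deliberately not part of
this package: pre-filter your FASTA with an external tool if your dataset
contains near-identical sequences (a 60% identity cutoff is a common choice
for this task).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)
AMBIGUOUS_RESIDUES = frozenset("BJOXUZ")

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUOUS_RESIDUES",
    "ProteinSequence",
    "LabeledDataset",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "clean_sequence",
    "clean_dataset",
    "read_labels",
    "write_labels",
    "load_labeled_dataset",
]


class FastaError(ValueError):
    """Raised for malformed FASTA input or inconsistent labels."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence.

    ``id`` is the FASTA header token up to the first whitespace; ``residues``
    is the residue string (upper case). After :func:`clean_sequence` the
    residues are guaranteed to lie in the 20-letter alphabet.
    """

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences paired with binary class labels (1 = positive, 0 = negative)."""

    sequences: list[ProteinSequence]
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels and len(self.labels) != len(self.sequences):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records.

    Residues are upper-cased but otherwise preserved (cleaning is a separate
    step). Raises :class:`FastaError` on a sequence line before any header or
    on duplicate identifiers.
    """
    path = Path(path)
    # Biopython tolerates leading junk lines; detect them explicitly so the
    # error can name the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno} contains sequence data before any"
                    " '>' header"
                )
            break
    records = [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    duplicates = sorted(name for name, n in seen.items() if n > 1)
    if duplicates:
        raise FastaError(f"{path}: duplicate sequence ids: {', '.join(duplicates)}")
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences to ``path`` in FASTA format (60-column wrapping)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def clean_sequence(raw: str) -> str:
    """Remove the ambiguous residue codes B, J, O, X, U, Z from ``raw``.

    ``raw`` must be an upper-case letter string; any non-letter character is
    an error. The result may be shorter than two residues — the caller
    decides whether to drop such sequences.
    """
    for ch in raw:
        if not ("A" <= ch <= "Z"):
            raise ValueError(f"invalid character {ch!r} in sequence")
    return "".join(ch for ch in raw if ch not in AMBIGUOUS_RESIDUES)


def clean_dataset(
    sequences: Sequence[ProteinSequence],
    labels: Sequence[int] | None = None,
    min_length: int = 2,
) -> LabeledDataset:
    """Clean every sequence, dropping those shorter than ``min_length`` after
    cleaning (a warning names each dropped id)."""
    kept: list[ProteinSequence] = []
    kept_labels: list[int] = []
    for i, seq in enumerate(sequences):
        cleaned = clean_sequence(seq.residues.upper())
        if len(cleaned) < min_length:
            warnings.warn(
                f"dropping sequence {seq.id!r}: only {len(cleaned)} residues"
                f" remain after cleaning (need >= {min_length})",
                stacklevel=2,
            )
            continue
        kept.append(ProteinSequence(seq.id, cleaned))
        if labels is not None:
            kept_labels.append(int(labels[i]))
    return LabeledDataset(kept, kept_labels if labels is not None else [])


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>{1|0}`` label file."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise FastaError(
                    f"{path}: line {lineno}: expected 'id<TAB>0|1', got {line!r}"
                )
            if parts[0] in labels:
                raise FastaError(f"{path}: duplicate label for id {parts[0]!r}")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq, lab in zip(dataset.sequences, dataset.labels):
            fh.write(f"{seq.id}\t{lab}\n")


def load_labeled_dataset(
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    clean: bool = True,
) -> LabeledDataset:
    """Read FASTA (and optionally a label file), clean, and pair labels.

    Every sequence id must appear in the label file when one is given.
    """
    sequences = read_fasta(fasta_path)
    labels: list[int] | None = None
    if labels_path is not None:
        table = read_labels(labels_path)
        missing = [s.id for s in sequences if s.id not in table]
        if missing:
            raise FastaError(
                f"{labels_path}: no label for ids: {', '.join(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        labels = [table[s.id] for s in sequences]
    if clean:
        return clean_dataset(sequences, labels)
    return LabeledDataset(list(sequences), labels if labels is not None else [])
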