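"""FASTA and feature-table I/O, sequence validation, labeled dataset assembly.

Sequences are canonicalized to uppercase strings over the 20 standard
one-letter amino-acid codes.  Records containing other characters (B, J, O,
U, X, Z, gaps, ``*``) are by default rejected with a per-record warning;
``sanitize=True`` instead strips the offending characters before validation.
Labels are positive=1 (phage virion protein), negative=0 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import AMINO_ACIDS

logger = logging.getLogger(__name__)

_VALID = frozenset(AMINO_ACIDS)


class FastaParseError(ValueError):
    """Raised when a file cannot be parsed as FASTA."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the 20 standard residues, uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledSequenceSet:
    """Positive (label 1) and negative (label 0) sequence subsets."""

    positives: tuple[ProteinSequence, ...]
    negatives: tuple[ProteinSequence, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.positives] + [s.id for s in self.negatives]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate sequence ids: {', '.join(dupes)}")

    @property
    def sequences(self) -> tuple[ProteinSequence, ...]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def _canonicalize(record_id: str, raw: str, sanitize: bool) -> ProteinSequence | None:
    seq = raw.upper().replace("-", "").replace(".", "").replace("*", "")
    bad = set(seq) - _VALID
    if bad:
        if not sanitize:
            logger.warning(
                "rejecting record %r: non-standard residues %s",
                record_id,
                "".join(sorted(bad)),
            )
            return None
        seq = "".join(c for c in seq if c in _VALID)
    if not seq:
        logger.warning("rejecting record %r: empty after canonicalization", record_id)
        return None
    return ProteinSequence(id=record_id, residues=seq)


def read_fasta(path: str | Path, sanitize: bool = False) -> list[ProteinSequence]:
    """Read a FASTA file into canonicalized :class:`ProteinSequence` records.

    Header text up to the first whitespace becomes the id; wrapped sequence
    lines are joined and uppercased.  Records with non-standard residues are
    dropped with a warning unless ``sanitize`` is set, in which case the
    offending characters are deleted.  An empty file yields an empty list
    (with a warning); sequence data before the first header is a parse error.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
        break
    else:
        logger.warning("%s: empty FASTA file", path)
        return []

    out: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _canonicalize(record.id, str(record.seq), sanitize)
        if seq is not None:
            out.append(seq)
    return out


def write_fasta(sequences: list[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as line-wrapped FASTA (inverse of :func:`read_fasta`)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def load_labeled_set(
    pos_path: str | Path, neg_path: str | Path, sanitize: bool = False
) -> LabeledSequenceSet:
    """Assemble a labeled dataset from positive and negative FASTA files.

    Duplicate ids across the two files are an error (the offenders are
    listed); in-file parsing follows :func:`read_fasta`.
    """
    positives = read_fasta(pos_path, sanitize=sanitize)
    negatives = read_fasta(neg_path, sanitize=sanitize)
    return LabeledSequenceSet(positives=tuple(positives), negatives=tuple(negatives))


def write_feature_table(
    matrix: np.ndarray,
    names: list[str],
    ids: list[str],
    path: str | Path,
) -> None:
    """Write a feature matrix as CSV: header of feature names, id first column."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(names):
        raise ValueError(
            f"matrix has {matrix.shape[1] if matrix.ndim == 2 else '?'} columns, "
            f"expected {len(names)}"
        )
    if matrix.shape[0] != len(ids):
        raise ValueError(f"{matrix.shape[0]} rows but {len(ids)} ids")
    df = pd.DataFrame(matrix, columns=names, index=pd.Index(ids, name="id"))
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a feature table written by :func:`write_feature_table`.

    Returns ``(ids, feature_names, matrix)``.
    """
    df = pd.read_csv(path, index_col=0)
    return list(df.index.astype(str)), list(df.columns), df.to_numpy(dtype=float)
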