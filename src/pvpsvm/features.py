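"""Hybrid 583-dimensional sequence encoding.

A protein sequence is mapped to the concatenation of five descriptor blocks,
in this fixed order:

====== ==== =========================================================
block  size contents
====== ==== =========================================================
AAC      20 amino-acid composition, alphabetical residue order
ATC       5 atomic composition: fractions of C, H, N, O, S atoms
CTD     147 composition/transition/distribution over 7 properties
DPC     400 overlapping dipeptide composition, alphabetical order
PCP      11 10 physicochemical class fractions + rescaled mean mass
====== ==== =========================================================

Every component lies in [0, 1].  AAC, ATC and DPC are frequency vectors
summing to 1 (DPC requires length >= 2).  For each CTD property the layout
per property is: 3 composition values (fraction of residues per group),
3 transition values (adjacent residue pairs crossing each unordered group
pair, divided by length-1), and 15 distribution values (for each group, the
1-based positions — as fractions of sequence length — of the first residue
and of the residues at which 25/50/75/100% of that group's occurrences are
reached; an absent group contributes five zeros).  The PCP mass term is the
mean residue mass min-max rescaled over the residue-mass range so encoding
stays local to the sequence.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .properties import (
    AMINO_ACIDS,
    ATOM_TYPES,
    CTD_PROPERTIES,
    PCP_CLASSES,
    ResiduePropertyTables,
    default_tables,
)
from .seq_io import LabeledSequenceSet, ProteinSequence

N_FEATURES = 583

_DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]
_GROUP_PAIRS = ((0, 1), (0, 2), (1, 2))
_DIST_POINTS = ("first", "25", "50", "75", "100")

#: (start, stop) slices of each block within the 583-vector, in layout order.
BLOCKS: dict[str, slice] = {
    "AAC": slice(0, 20),
    "ATC": slice(20, 25),
    "CTD": slice(25, 172),
    "DPC": slice(172, 572),
    "PCP": slice(572, 583),
}


def feature_names() -> list[str]:
    """The 583 feature names in fixed layout order."""
    names = [f"AAC_{aa}" for aa in AMINO_ACIDS]
    names += [f"ATC_{a}" for a in ATOM_TYPES]
    for prop in CTD_PROPERTIES:
        names += [f"CTD_{prop}_C_g{g}" for g in (1, 2, 3)]
        names += [f"CTD_{prop}_T_g{a + 1}g{b + 1}" for a, b in _GROUP_PAIRS]
        for g in (1, 2, 3):
            names += [f"CTD_{prop}_D_g{g}_{pt}" for pt in _DIST_POINTS]
    names += [f"DPC_{dp}" for dp in _DIPEPTIDES]
    names += [f"PCP_{c}" for c in PCP_CLASSES]
    names.append("PCP_mass")
    assert len(names) == N_FEATURES
    return names


def feature_block(name: str) -> str:
    """Block tag (AAC/ATC/CTD/DPC/PCP) of a feature name."""
    return name.split("_", 1)[0]


def compute_aac(seq: ProteinSequence) -> np.ndarray:
    """Amino-acid composition: per-residue frequency, alphabetical order."""
    n = len(seq)
    counts = np.array([seq.residues.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return counts / n


def compute_dpc(seq: ProteinSequence) -> np.ndarray:
    """Dipeptide composition: overlapping pair frequency over length-1 windows."""
    if len(seq) < 2:
        raise ValueError(f"sequence {seq.id!r}: DPC requires length >= 2")
    counts = np.zeros(400)
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    r = seq.residues
    for a, b in zip(r, r[1:]):
        counts[idx[a] * 20 + idx[b]] += 1
    return counts / (len(seq) - 1)


def compute_atc(
    seq: ProteinSequence, tables: ResiduePropertyTables | None = None
) -> np.ndarray:
    """Atomic composition: fractions of C, H, N, O, S atoms over the chain.

    Uses peptide-bonded residue formulas plus one terminal water per chain.
    """
    tables = tables or default_tables()
    totals = np.zeros(5)
    for aa in seq.residues:
        counts = tables.atom_counts[aa]
        totals += [counts[a] for a in ATOM_TYPES]
    totals[ATOM_TYPES.index("H")] += 2  # terminal H2O
    totals[ATOM_TYPES.index("O")] += 1
    return totals / totals.sum()


def _distribution(positions: list[int], length: int) -> list[float]:
    """First/25/50/75/100% occurrence positions as fractions of length."""
    n_g = len(positions)
    if n_g == 0:
        return [0.0] * 5
    out = [positions[0] / length]
    for p in (0.25, 0.5, 0.75, 1.0):
        k = math.ceil(p * n_g)
        out.append(positions[k - 1] / length)
    return out


def compute_ctd(
    seq: ProteinSequence, tables: ResiduePropertyTables | None = None
) -> np.ndarray:
    """Composition/transition/distribution descriptor (7 properties x 21)."""
    tables = tables or default_tables()
    n = len(seq)
    out: list[float] = []
    for prop in CTD_PROPERTIES:
        groups = tables.ctd_groups[prop]
        labels = [next(g for g in range(3) if aa in groups[g]) for aa in seq.residues]
        # composition
        group_counts = [labels.count(g) for g in range(3)]
        out.extend(c / n for c in group_counts)
        # transition: adjacent pairs crossing each unordered group pair
        if n == 1:
            out.extend([0.0, 0.0, 0.0])
        else:
            for a, b in _GROUP_PAIRS:
                t = sum(
                    1
                    for x, y in zip(labels, labels[1:])
                    if {x, y} == {a, b}
                )
                out.append(t / (n - 1))
        # distribution: 1-based occurrence positions per group
        for g in range(3):
            positions = [i + 1 for i, lab in enumerate(labels) if lab == g]
            out.extend(_distribution(positions, n))
    return np.array(out)


def compute_pcp(
    seq: ProteinSequence, tables: ResiduePropertyTables | None = None
) -> np.ndarray:
    """Physicochemical class fractions plus min-max-rescaled mean residue mass."""
    tables = tables or default_tables()
    n = len(seq)
    out = [
        sum(1 for aa in seq.residues if aa in tables.pcp_classes[c]) / n
        for c in PCP_CLASSES
    ]
    mean_mass = sum(tables.residue_masses[aa] for aa in seq.residues) / n
    lo, hi = tables.mass_range
    out.append((mean_mass - lo) / (hi - lo))
    return np.array(out)


def encode(
    seq: ProteinSequence, tables: ResiduePropertyTables | None = None
) -> np.ndarray:
    """Full 583-component hybrid feature vector (AAC|ATC|CTD|DPC|PCP)."""
    tables = tables or default_tables()
    vec = np.concatenate(
        [
            compute_aac(seq),
            compute_atc(seq, tables),
            compute_ctd(seq, tables),
            compute_dpc(seq),
            compute_pcp(seq, tables),
        ]
    )
    assert vec.shape == (N_FEATURES,)
    return vec


def encode_set(
    dataset: LabeledSequenceSet, tables: ResiduePropertyTables | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a labeled set: rows are positives then negatives, labels 1 then 0.

    Raises on the first invalid sequence, naming it.
    """
    tables = tables or default_tables()
    rows = []
    for s in dataset.sequences:
        try:
            rows.append(encode(s, tables))
        except ValueError as exc:
            raise ValueError(f"cannot encode sequence {s.id!r}: {exc}") from exc
    X = np.vstack(rows) if rows else np.empty((0, N_FEATURES))
    return X, dataset.labels
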