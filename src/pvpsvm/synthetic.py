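"""Synthetic labeled protein-sequence generator with a planted signal.

Sequences are drawn i.i.d. per position from class-specific residue
distributions.  The background is uniform over the 20 residues (a natural
amino-acid frequency table is available for more realistic composition);
positives multiply the probability of each *signal residue* by an
``enrichment`` factor (then renormalize) and may additionally carry a
*dipeptide signal*: at each construction step a positive sequence emits the
signal dipeptide with a fixed per-step probability instead of a single
background-drawn residue.  With ``enrichment = 1`` and no dipeptide signal
the two classes are exchangeable — the null scenario used to detect leakage
in the selection/evaluation machinery.

Sequence lengths are uniform over a range, identically for both classes, so
no length or mass signal leaks the label by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .properties import AMINO_ACIDS
from .seq_io import LabeledSequenceSet, ProteinSequence, write_fasta

#: Approximate natural amino-acid frequencies (UniProt-like background).
NATURAL_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic labeled-dataset draw."""

    n_pos: int = 30
    n_neg: int = 60
    length_range: tuple[int, int] = (100, 300)
    signal_residues: str = "KR"
    enrichment: float = 2.5
    dipeptide_signal: str | None = "KR"
    dipeptide_rate: float = 0.05
    background: str = "uniform"  # uniform | natural
    seed: int = 101

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if self.dipeptide_signal is not None and len(self.dipeptide_signal) != 2:
            raise ValueError("dipeptide signal must have length 2")
        if not 0 <= self.dipeptide_rate < 1:
            raise ValueError("dipeptide rate must be in [0, 1)")
        if self.background not in ("uniform", "natural"):
            raise ValueError("background must be 'uniform' or 'natural'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        d = json.loads(text)
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


def _background_probs(scenario: SyntheticScenario) -> np.ndarray:
    if scenario.background == "uniform":
        return np.full(20, 1 / 20)
    return np.array([NATURAL_FREQUENCIES[aa] for aa in AMINO_ACIDS])


def class_distributions(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) per-position residue distributions."""
    neg = _background_probs(scenario)
    if scenario.enrichment == 1:
        return neg.copy(), neg  # exactly exchangeable null
    pos = neg.copy()
    for aa in scenario.signal_residues:
        pos[AMINO_ACIDS.index(aa)] *= scenario.enrichment
    pos = pos / pos.sum()
    return pos, neg


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    dipeptide: str | None,
    dipeptide_rate: float,
) -> str:
    chars: list[str] = []
    while len(chars) < length:
        if (
            dipeptide is not None
            and len(chars) <= length - 2
            and rng.random() < dipeptide_rate
        ):
            chars.extend(dipeptide)
        else:
            chars.append(AMINO_ACIDS[rng.choice(20, p=probs)])
    return "".join(chars[:length])


def generate(scenario: SyntheticScenario) -> LabeledSequenceSet:
    """Draw a labeled sequence set; byte-identical for identical scenarios."""
    rng = np.random.default_rng(scenario.seed)
    pos_probs, neg_probs = class_distributions(scenario)
    lo, hi = scenario.length_range

    positives = []
    for i in range(scenario.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = _draw_sequence(
            rng, length, pos_probs, scenario.dipeptide_signal, scenario.dipeptide_rate
        )
        positives.append(ProteinSequence(id=f"pos_{i + 1:04d}", residues=seq))
    negatives = []
    for i in range(scenario.n_neg):
        length = int(rng.integers(lo, hi + 1))
        seq = _draw_sequence(rng, length, neg_probs, None, 0.0)
        negatives.append(ProteinSequence(id=f"neg_{i + 1:04d}", residues=seq))
    return LabeledSequenceSet(positives=tuple(positives), negatives=tuple(negatives))


def write_scenario(
    scenario: SyntheticScenario, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate and write paired FASTA files plus a scenario JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = generate(scenario)
    pos_path = out_dir / "positives.fasta"
    neg_path = out_dir / "negatives.fasta"
    meta_path = out_dir / "scenario.json"
    write_fasta(list(dataset.positives), pos_path)
    write_fasta(list(dataset.negatives), neg_path)
    meta_path.write_text(scenario.to_json() + "\n")
    return pos_path, neg_path, meta_path


def acceptance_scenario(seed: int = 101) -> SyntheticScenario:
    """The fixed scenario used by the package's own acceptance checks.

    90 sequences at the roughly 1:2 positive:negative imbalance typical of
    virion-protein datasets, lengths 100-300, lysine/arginine enrichment 2.5
    in positives plus a boosted KR dipeptide.  Only the seed varies.
    """
    return SyntheticScenario(
        n_pos=30,
        n_neg=60,
        length_range=(100, 300),
        signal_residues="KR",
        enrichment=2.5,
        dipeptide_signal="KR",
        dipeptide_rate=0.05,
        background="uniform",
        seed=seed,
    )


def null_scenario(seed: int = 0, n_pos: int = 20, n_neg: int = 20) -> SyntheticScenario:
    """Exchangeable-classes scenario (no signal) for leakage checks."""
    return SyntheticScenario(
        n_pos=n_pos,
        n_neg=n_neg,
        length_range=(100, 300),
        signal_residues="KR",
        enrichment=1.0,
        dipeptide_signal=None,
        dipeptide_rate=0.0,
        background="uniform",
        seed=seed,
    )
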