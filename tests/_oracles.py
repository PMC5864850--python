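"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: counting is done with
plain Python loops and dictionaries, the ATC atom table is re-derived here
from free-amino-acid molecular formulas, and LOOCV is a literal
slice-refit-predict loop.
"""

from __future__ import annotations

import math
import re
from collections import Counter

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Free amino-acid molecular formulas; the peptide-bonded residue is the free
# molecule minus one water, and one terminal water is restored per chain.
FREE_AA_FORMULAS = {
    "A": "C3H7NO2", "R": "C6H14N4O2", "N": "C4H8N2O3", "D": "C4H7NO4",
    "C": "C3H7NO2S", "E": "C5H9NO4", "Q": "C5H10N2O3", "G": "C2H5NO2",
    "H": "C6H9N3O2", "I": "C6H13NO2", "L": "C6H13NO2", "K": "C6H14N2O2",
    "M": "C5H11NO2S", "F": "C9H11NO2", "P": "C5H9NO2", "S": "C3H7NO3",
    "T": "C4H9NO3", "V": "C5H11NO2", "W": "C11H12N2O2", "Y": "C9H11NO3",
}


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for elem, num in re.findall(r"([A-Z])(\d*)", formula):
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


def oracle_aac(seq: str) -> np.ndarray:
    c = Counter(seq)
    return np.array([c[aa] / len(seq) for aa in ALPHABET])


def oracle_dpc(seq: str) -> np.ndarray:
    windows = [seq[i : i + 2] for i in range(len(seq) - 1)]
    c = Counter(windows)
    return np.array([c[a + b] / len(windows) for a in ALPHABET for b in ALPHABET])


def oracle_atc(seq: str) -> np.ndarray:
    totals = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    for aa in seq:
        f = parse_formula(FREE_AA_FORMULAS[aa])
        f["H"] -= 2  # remove water per bonded residue
        f["O"] -= 1
        for k in totals:
            totals[k] += f.get(k, 0)
    totals["H"] += 2  # one terminal water per chain
    totals["O"] += 1
    grand = sum(totals.values())
    return np.array([totals[k] / grand for k in ("C", "H", "N", "O", "S")])


def oracle_ctd(seq: str, ctd_groups, property_order) -> np.ndarray:
    """Enumerates groups, adjacent pairs, and cumulative occurrence positions."""
    n = len(seq)
    out = []
    for prop in property_order:
        groups = ctd_groups[prop]
        lab = []
        for aa in seq:
            for g in range(3):
                if aa in groups[g]:
                    lab.append(g)
                    break
        for g in range(3):  # composition
            out.append(lab.count(g) / n)
        for a, b in ((0, 1), (0, 2), (1, 2)):  # transitions
            if n == 1:
                out.append(0.0)
            else:
                t = 0
                for i in range(n - 1):
                    if (lab[i] == a and lab[i + 1] == b) or (
                        lab[i] == b and lab[i + 1] == a
                    ):
                        t += 1
                out.append(t / (n - 1))
        for g in range(3):  # distribution
            pos = [i + 1 for i in range(n) if lab[i] == g]
            if not pos:
                out.extend([0.0] * 5)
                continue
            out.append(pos[0] / n)
            for frac in (0.25, 0.5, 0.75, 1.0):
                out.append(pos[math.ceil(frac * len(pos)) - 1] / n)
    return np.array(out)


def oracle_pcp(seq: str, pcp_classes, class_order, masses) -> np.ndarray:
    out = []
    for cls in class_order:
        members = pcp_classes[cls]
        out.append(sum(1 for aa in seq if aa in members) / len(seq))
    mean_mass = sum(masses[aa] for aa in seq) / len(seq)
    lo, hi = min(masses.values()), max(masses.values())
    out.append((mean_mass - lo) / (hi - lo))
    return np.array(out)


def oracle_loocv(trainer, X: np.ndarray, y: np.ndarray):
    """Literal slice-refit-predict loop."""
    n = len(y)
    preds, scores = np.empty(n), np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        model = trainer(X[keep], y[keep])
        p, s = model.predict(X[i : i + 1])
        preds[i], scores[i] = p[0], s[0]
    return preds, scores


def oracle_metrics(tp: int, tn: int, fp: int, fn: int):
    """Direct evaluation of the four confusion-count formulas."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return sens, spec, acc, mcc


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))
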