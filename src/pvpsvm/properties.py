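"""Residue property tables backing the ATC, CTD and PCP encoders.

The tables ship with the package as plain-text TSV files under
``pvpsvm/data/`` so that they can be inspected, cited and, if needed,
overridden.  :func:`load_tables` parses them once and returns an immutable
:class:`ResiduePropertyTables` bundle; the module-level :func:`default_tables`
caches that bundle for the common case.

Conventions baked into the shipped tables
-----------------------------------------
* Atom counts are for the *peptide-bonded* residue (free amino acid minus one
  water); the encoder adds one terminal water per chain.
* Residue masses are average (not monoisotopic) masses of the bonded residue.
* Each CTD property's three groups partition the 20-letter alphabet exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
ATOM_TYPES: tuple[str, ...] = ("C", "H", "N", "O", "S")

#: CTD properties in fixed layout order.
CTD_PROPERTIES: tuple[str, ...] = (
    "hydrophobicity",
    "normalized_vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "secondary_structure",
    "solvent_accessibility",
)

#: PCP class attributes in fixed layout order (mass term appended last).
PCP_CLASSES: tuple[str, ...] = (
    "polar",
    "hydrophobic",
    "charged",
    "aliphatic",
    "aromatic",
    "positively_charged",
    "negatively_charged",
    "small",
    "tiny",
    "large",
)


@dataclass(frozen=True)
class ResiduePropertyTables:
    """Bundle of residue-level lookup tables used by the encoders."""

    atom_counts: dict[str, dict[str, int]]
    ctd_groups: dict[str, tuple[frozenset[str], frozenset[str], frozenset[str]]]
    pcp_classes: dict[str, frozenset[str]]
    residue_masses: dict[str, float]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        alphabet = set(AMINO_ACIDS)
        for prop, groups in self.ctd_groups.items():
            union = set().union(*groups)
            if union != alphabet or sum(len(g) for g in groups) != 20:
                raise ValueError(
                    f"CTD property {prop!r}: groups do not partition the "
                    f"20-residue alphabet"
                )
        for aa in AMINO_ACIDS:
            counts = self.atom_counts[aa]
            if any(counts[a] <= 0 for a in ("C", "H", "N", "O")):
                raise ValueError(f"residue {aa}: C/H/N/O counts must be positive")
            if counts["S"] != 0 and aa not in "CM":
                raise ValueError(f"residue {aa}: unexpected sulfur content")

    @property
    def mass_range(self) -> tuple[float, float]:
        masses = self.residue_masses.values()
        return min(masses), max(masses)


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_tables(data_dir: str | Path | None = None) -> ResiduePropertyTables:
    """Parse the property tables from ``data_dir`` (default: packaged data).

    Users may point this at a directory containing files with the same names
    and layout as the shipped ones to override any table.
    """
    if data_dir is None:
        data_dir = Path(str(importlib.resources.files("pvpsvm").joinpath("data")))
    data_dir = Path(data_dir)

    rows = _read_tsv(data_dir / "atom_counts.tsv")
    header, body = rows[0], rows[1:]
    atom_counts = {
        r[0]: {atom: int(v) for atom, v in zip(header[1:], r[1:])} for r in body
    }

    rows = _read_tsv(data_dir / "ctd_groups.tsv")
    ctd_groups = {
        r[0]: (frozenset(r[1]), frozenset(r[2]), frozenset(r[3])) for r in rows[1:]
    }

    rows = _read_tsv(data_dir / "pcp_classes.tsv")
    pcp_classes = {r[0]: frozenset(r[1]) for r in rows[1:]}

    rows = _read_tsv(data_dir / "residue_masses.tsv")
    residue_masses = {r[0]: float(r[1]) for r in rows[1:]}

    version_file = data_dir / "VERSION.txt"
    version = (
        version_file.read_text().strip() if version_file.exists() else "unversioned"
    )
    return ResiduePropertyTables(
        atom_counts=atom_counts,
        ctd_groups=ctd_groups,
        pcp_classes=pcp_classes,
        residue_masses=residue_masses,
        version=version,
    )


_DEFAULT: ResiduePropertyTables | None = None


def default_tables() -> ResiduePropertyTables:
    """Cached tables parsed from the packaged data files."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_tables()
    return _DEFAULT
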