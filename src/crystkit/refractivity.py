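"""Additive (Gladstone–Dale) refractive-index-increment model for proteins.

A protein's dn/dc is modelled as the mass-fraction-weighted average of
per-residue refractive index increments.  The per-residue table ships as a
swappable TSV (residue, dn/dc in mL/g, residue mass in g/mol); residue masses
are free amino acid minus one water.  The Arg (0.206 mL/g) and Lys
(0.181 mL/g) increments are the load-bearing values for the lens-crystallin
question: an Arg-for-Lys substitution raises refractivity at constant charge.

An optional additive correction hook is provided for interactions between
pairs of aromatic residues, which additive models neglect; no published
functional form ships, so it is OFF by default and user-supplied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

AROMATIC = set("FWY")


@dataclass(frozen=True)
class ResidueEntry:
    dndc: float  # mL/g
    mass: float  # g/mol, residue (free amino acid minus water)
    source: str


@dataclass
class ResidueRefractivityTable:
    entries: dict[str, ResidueEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.entries)
        if missing:
            raise ValueError(f"refractivity table missing residues {sorted(missing)}")
        for aa, e in self.entries.items():
            if e.dndc <= 0 or e.mass <= 0:
                raise ValueError(f"non-positive table entry for {aa}")

    def dndc(self, residue: str) -> float:
        try:
            return self.entries[residue].dndc
        except KeyError:
            raise ValueError(f"unknown residue code {residue!r}") from None

    def mass(self, residue: str) -> float:
        try:
            return self.entries[residue].mass
        except KeyError:
            raise ValueError(f"unknown residue code {residue!r}") from None


@dataclass(frozen=True)
class ProteinRefractivity:
    id: str
    dndc: float  # mL/g
    mass_fractions: dict[str, float]


def load_refractivity_table(path=None) -> ResidueRefractivityTable:
    """Load the per-residue dn/dc table (packaged default, or a user TSV)."""
    if path is None:
        text = (resources.files("crystkit.data")
                / "residue_refractivity.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = {}
    lines = text.strip().splitlines()
    for line in lines[1:]:
        aa, dndc, mass, source = line.split("\t")
        entries[aa] = ResidueEntry(dndc=float(dndc), mass=float(mass), source=source)
    return ResidueRefractivityTable(entries=entries)


_DEFAULT_TABLE: ResidueRefractivityTable | None = None


def default_table() -> ResidueRefractivityTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_refractivity_table()
    return _DEFAULT_TABLE


def residue_dndc(residue: str, table: ResidueRefractivityTable | None = None) -> float:
    """Per-residue refractive index increment (mL/g)."""
    return (table or default_table()).dndc(residue)


def protein_dndc(
    seq: str,
    table: ResidueRefractivityTable | None = None,
    record_id: str = "",
    ignore_unknown: bool = False,
    aromatic_pair_coeff: float = 0.0,
    aromatic_pair_window: int = 10,
) -> ProteinRefractivity:
    """Gladstone–Dale dn/dc of a protein: Σ w_i · (dn/dc)_i over residue
    types, with w_i the mass fraction of type i.

    ``X`` residues raise unless ``ignore_unknown`` is set (then excluded from
    both numerator and denominator, with a warning).  When
    ``aromatic_pair_coeff`` is nonzero, an additive term
    ``coeff × (#aromatic pairs within aromatic_pair_window residues) / n``
    is applied as a user-parameterised correction for aromatic-pair
    interactions.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    tab = table or default_table()
    if "X" in seq:
        if not ignore_unknown:
            raise ValueError(
                "sequence contains X; pass ignore_unknown=True to exclude"
            )
        import warnings

        warnings.warn("excluding X residues from dn/dc", stacklevel=2)
        seq = seq.replace("X", "")
        if not seq:
            raise ValueError("sequence contains only X residues")
    counts = Counter(seq)
    masses = {aa: n * tab.mass(aa) for aa, n in counts.items()}
    total_mass = sum(masses.values())
    fractions = {aa: m / total_mass for aa, m in masses.items()}
    dndc = sum(frac * tab.dndc(aa) for aa, frac in fractions.items())
    if aromatic_pair_coeff:
        npairs = _aromatic_pairs(seq, aromatic_pair_window)
        dndc += aromatic_pair_coeff * npairs / len(seq)
    return ProteinRefractivity(id=record_id, dndc=dndc, mass_fractions=fractions)


def _aromatic_pairs(seq: str, window: int) -> int:
    positions = [i for i, aa in enumerate(seq) if aa in AROMATIC]
    return sum(
        1
        for a in range(len(positions))
        for b in range(a + 1, len(positions))
        if positions[b] - positions[a] <= window
    )
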