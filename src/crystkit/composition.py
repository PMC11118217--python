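"""Amino-acid composition statistics for crystallins.

Counts and percentages of Cys and Met per protein, Lys/Arg and Ala/Cys
ratios, and unweighted subfamily averages.  Mature eukaryotic proteins have
their initiator Met excluded from counts (it is cleaved post-translationally),
while percentage denominators use the full stored length — the convention
under which the published per-protein and group values reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_core import SequenceRecord, Table1Fixture, PROTEIN_ALPHABET

CANONICAL20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CompositionRow:
    id: str
    length: int
    cys_count: int
    cys_pct: float
    met_count: int
    met_pct: float
    kr_ratio: float | None
    ala_cys_ratio: float | None


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_cys_pct: float
    mean_met_pct: float


def percentage(count: int, length: int) -> float:
    """Residue percentage as reported: count/length × 100, rounded
    half-to-even to one decimal."""
    if length <= 0:
        raise ValueError("length must be positive")
    return round(count / length * 100, 1)


def count_residue(seq: str, residue: str, mature: bool = False) -> int:
    """Count occurrences of ``residue`` in ``seq``.

    With ``mature=True``, an initiator Met (position 1) is excluded when
    counting M, reflecting its cleavage in mature eukaryotic proteins.
    """
    if residue not in CANONICAL20:
        raise ValueError(f"non-canonical residue {residue!r}")
    seq = seq.upper()
    n = seq.count(residue)
    if mature and residue == "M" and seq.startswith("M"):
        n -= 1
    return n


def composition_row(record: SequenceRecord) -> CompositionRow:
    """Full composition statistics for one protein record.

    Ratios are ``None`` when the denominator count is zero.  Percentages are
    rounded half-to-even to one decimal; ratios to three decimals.
    """
    if record.moltype != "protein":
        raise ValueError(f"{record.id}: composition requires a protein record")
    if not record.seq:
        raise ValueError(f"{record.id}: empty sequence")
    length = len(record.seq)
    cys = count_residue(record.seq, "C", mature=record.mature)
    met = count_residue(record.seq, "M", mature=record.mature)
    lys = count_residue(record.seq, "K")
    arg = count_residue(record.seq, "R")
    ala = count_residue(record.seq, "A")
    return CompositionRow(
        id=record.id,
        length=length,
        cys_count=cys,
        cys_pct=percentage(cys, length),
        met_count=met,
        met_pct=percentage(met, length),
        kr_ratio=round(lys / arg, 3) if arg else None,
        ala_cys_ratio=round(ala / cys, 3) if cys else None,
    )


def residue_counts(seq: str, mature: bool = False) -> dict[str, int]:
    """Counts for all 20 canonical residues (X excluded)."""
    return {aa: count_residue(seq, aa, mature=mature) for aa in CANONICAL20}


def group_means(table, group: str) -> GroupSummary:
    """Unweighted arithmetic mean of member Cys/Met percentages for a group.

    ``table`` is either a :class:`Table1Fixture` or a list of
    :class:`CompositionRow` paired with group labels as ``(row, group)``.
    """
    if isinstance(table, Table1Fixture):
        members = [(r.cys_pct, r.met_pct) for r in table.block_rows(group)]
    else:
        members = [(row.cys_pct, row.met_pct) for row, g in table if g == group]
    if not members:
        raise ValueError(f"group {group!r} is empty")
    n = len(members)
    return GroupSummary(
        group=group,
        n=n,
        mean_cys_pct=round(sum(c for c, _ in members) / n, 1),
        mean_met_pct=round(sum(m for _, m in members) / n, 1),
    )


def format_ratio(value: float | None) -> str:
    """Render a decimal quotient in the '1:n' style (e.g. 0.25 -> '1:4.0')."""
    if value is None:
        return "NA"
    if value == 0:
        return "0:1"
    return f"1:{1 / value:.1f}"
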