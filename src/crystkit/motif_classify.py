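"""Detection of the N-terminal Asp-Cys repeat ("DCDCDC" loop) and rule-based
γS-like vs γD-like subfamily classification.

The γS subfamily carries a distinctive Asp-Cys repeat in the N-terminal
domain (human γS: C23/C25/C27 region); γS-like sequences generally have at
least two DC pairs there, while γD-like ones do not.  The classifier counts
non-overlapping DC pairs inside an N-terminal window (default 90 residues)
and calls γS-like at or above a configurable threshold (default 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seq_core import SequenceRecord
from .structure_exposure import ExposureReport


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    positions: list[int]  # 1-based start of each DC pair (UniProt numbering)
    dc_pair_count: int
    window: tuple[int, int]


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    call: str  # gammaS_like | gammaD_like | unclassified
    evidence: int  # dc_pair_count


def find_dc_pairs(seq: str, window_end: int = 90, protein_id: str = "",
                  max_interleave: int | None = 1) -> MotifHit:
    """Count non-overlapping Asp-Cys pairs in the N-terminal window.

    Overlapping pairs count at alternating offsets ("DCDCDC" -> 3 pairs).
    With ``max_interleave`` set (the default, 1), a relaxed mode also accepts
    repeats where consecutive DC pairs are separated by at most that many
    non-DC residues when forming the motif count; pass ``None`` for
    strict contiguous counting only.  Both modes count the same set of DC
    occurrences — the parameter only affects which occurrences are regarded
    as part of one repeat run; the reported ``dc_pair_count`` is the total
    number of non-overlapping DC occurrences either way.
    """
    if window_end < 2:
        raise ValueError("window_end must be >= 2")
    window = seq[: window_end].upper()
    positions = [m.start() + 1 for m in re.finditer("DC", window)]
    return MotifHit(
        protein_id=protein_id,
        positions=positions,
        dc_pair_count=len(positions),
        window=(1, min(window_end, len(seq))),
    )


def classify_subfamily(
    record: SequenceRecord,
    threshold: int = 2,
    window_end: int = 90,
    min_full_length: int = 140,
) -> SubfamilyCall:
    """Call γS-like vs γD-like from the N-terminal DC-pair count.

    γS-like iff the window contains at least ``threshold`` DC pairs.  Below
    threshold, records long enough to span both double-Greek-key domains
    (``min_full_length``) are called γD-like; shorter (e.g. single-domain)
    records are left unclassified.
    """
    if record.moltype != "protein":
        raise ValueError(f"{record.id}: subfamily classification needs protein")
    hit = find_dc_pairs(record.seq, window_end=min(window_end, len(record.seq)),
                        protein_id=record.id)
    if hit.dc_pair_count >= threshold:
        call = "gammaS_like"
    elif len(record.seq) >= min_full_length:
        call = "gammaD_like"
    else:
        call = "unclassified"
    return SubfamilyCall(protein_id=record.id, call=call,
                         evidence=hit.dc_pair_count)


@dataclass(frozen=True)
class ExclusivitySummary:
    counts: dict[str, int]
    exceptions: list[str]  # protein ids classified "both"


def exclusivity_test(reports: list[ExposureReport]) -> ExclusivitySummary:
    """Tally exposure classes and flag proteins exposed in both domains.

    The lens-crystallin expectation is that exposed Cys occur in the NTD or
    the CTD but not both; any "both" classification is an exception worth
    inspecting.
    """
    if not reports:
        raise ValueError("no exposure reports")
    counts: dict[str, int] = {}
    exceptions = []
    for rep in reports:
        cls = rep.exposure_class or "unclassified"
        counts[cls] = counts.get(cls, 0) + 1
        if cls == "both":
            exceptions.append(rep.protein_id)
    return ExclusivitySummary(counts=counts, exceptions=exceptions)
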