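"""Sequence data model, FASTA I/O, the packaged composition table, and the
inclusion/exclusion filter for crystallin datasets.

The central container is :class:`SequenceRecord`, holding one protein or
coding-sequence (CDS) entry together with its organism, subfamily group and
molecule type.  The packaged fixture (:func:`load_table1_fixture`) reproduces
the published per-protein cysteine/methionine census of chordate βγ- and
γ-crystallins: 42 proteins in four contiguous subfamily blocks (ancestral
βγ-like, γS, γD-like, and the fish-specific γM).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    ConfigurationError,
    DuplicateIdError,
    FastaParseError,
    FixtureIntegrityError,
    OfflineError,
)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUC_ALPHABET = set("ACGTUN-")
GROUPS = ("betagamma", "gammaS", "gammaD_like", "gammaM", "other")

# Table 1 subfamily blocks are contiguous in the published table, in this order.
BLOCK_ORDER = ("betagamma", "gammaS", "gammaD_like", "gammaM")


@dataclass
class SequenceRecord:
    """One protein or CDS entry.

    ``mature`` marks a eukaryotic protein whose initiator Met is cleaved in
    the mature form; composition counting uses it to exclude position 1.
    """

    id: str
    seq: str
    moltype: str = "protein"
    organism: str = ""
    protein_name: str = ""
    group: str = "other"
    description: str = ""
    mature: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord requires a non-empty id")
        if self.moltype not in ("protein", "cds"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        self.seq = self.seq.upper()
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else NUC_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"{self.id}: invalid {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The header line is split into the id (first whitespace-delimited token,
    without the leading ``>``) and a free-text description.  Entry order is
    preserved.  An empty file yields an empty list with a warning; text before
    the first header raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: expected FASTA header '>' before sequence data", lineno
            )
        break
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), moltype=moltype,
                           description=desc)
        )
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    """Write records as standard FASTA with 60-column line wrapping.

    Duplicate ids are rejected so the file can be read back unambiguously.
    """
    if not records:
        raise ValueError("write_fasta requires at least one record")
    ids = [r.id for r in records]
    dups = {i for i in ids if ids.count(i) > 1}
    if dups:
        raise DuplicateIdError(dups)
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def filter_crystallins(
    records: list[SequenceRecord],
    min_len: int = 80,
    max_len: int = 200,
    exclude_patterns: tuple[str, ...] = ("AIM",),
):
    """Apply the dataset inclusion filter: a length window standing in for the
    'complete Greek key domains' requirement, plus name-pattern exclusions for
    non-lens homologs (e.g. absent-in-melanoma-1).

    Returns ``(kept, excluded)`` where ``excluded`` is a list of
    ``(record, reason)`` pairs with machine-readable reasons: ``"truncated"``,
    ``"overlong"``, or ``"pattern:<p>"``.
    """
    if min_len > max_len:
        raise ConfigurationError(f"min_len {min_len} > max_len {max_len}")
    kept, excluded = [], []
    for rec in records:
        if rec.moltype != "protein":
            raise ValueError(f"{rec.id}: filter_crystallins expects protein records")
        reason = None
        for pat in exclude_patterns:
            if pat.lower() in rec.id.lower() or pat.lower() in rec.protein_name.lower() \
                    or pat.lower() in rec.description.lower():
                reason = f"pattern:{pat}"
                break
        if reason is None and len(rec) < min_len:
            reason = "truncated"
        if reason is None and len(rec) > max_len:
            reason = "overlong"
        if reason is None:
            kept.append(rec)
        else:
            excluded.append((rec, reason))
    return kept, excluded


@dataclass(frozen=True)
class Table1Row:
    organism: str
    protein_name: str
    uniprot_id: str
    method: int
    length: int
    cys_count: int
    cys_pct: float
    met_count: int
    met_pct: float
    block: str


@dataclass
class Table1Fixture:
    """The published per-protein Cys/Met census, with subfamily block labels."""

    rows: list[Table1Row] = field(default_factory=list)

    def block_rows(self, block: str) -> list[Table1Row]:
        return [r for r in self.rows if r.block == block]

    def block_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.block_rows(b)) for b in BLOCK_ORDER)

    def row(self, uniprot_id: str) -> Table1Row:
        for r in self.rows:
            if r.uniprot_id == uniprot_id:
                return r
        raise KeyError(uniprot_id)


def _fixture_text() -> str:
    return (resources.files("crystkit.data") / "table1.tsv").read_text()


def load_table1_fixture() -> Table1Fixture:
    """Load and validate the packaged composition table.

    Integrity checks enforced at load time:

    * every percentage equals ``round(count / length * 100, 1)``;
    * ids unique; block labels valid and contiguous in publication order.
    """
    text = _fixture_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    expected = ["organism", "protein", "uniprot_id", "method", "length",
                "cys_count", "cys_pct", "met_count", "met_pct", "block"]
    if header != expected:
        raise FixtureIntegrityError(f"unexpected fixture header: {header}")
    rows = []
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) != 10:
            raise FixtureIntegrityError(f"malformed fixture row: {line!r}")
        rows.append(Table1Row(
            organism=f[0], protein_name=f[1], uniprot_id=f[2], method=int(f[3]),
            length=int(f[4]), cys_count=int(f[5]), cys_pct=float(f[6]),
            met_count=int(f[7]), met_pct=float(f[8]), block=f[9],
        ))
    ids = [r.uniprot_id for r in rows]
    if len(set(ids)) != len(ids):
        raise FixtureIntegrityError("duplicate uniprot ids in fixture")
    seen_blocks = []
    for r in rows:
        if r.block not in BLOCK_ORDER:
            raise FixtureIntegrityError(f"{r.uniprot_id}: unknown block {r.block}")
        if not seen_blocks or seen_blocks[-1] != r.block:
            seen_blocks.append(r.block)
        if round(r.cys_count / r.length * 100, 1) != r.cys_pct:
            raise FixtureIntegrityError(
                f"{r.uniprot_id}: cys_pct {r.cys_pct} inconsistent with "
                f"{r.cys_count}/{r.length}"
            )
        if round(r.met_count / r.length * 100, 1) != r.met_pct:
            raise FixtureIntegrityError(
                f"{r.uniprot_id}: met_pct {r.met_pct} inconsistent with "
                f"{r.met_count}/{r.length}"
            )
    if tuple(seen_blocks) != BLOCK_ORDER:
        raise FixtureIntegrityError(
            f"blocks not contiguous in publication order: {seen_blocks}"
        )
    return Table1Fixture(rows=rows)


_UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch_uniprot(ids: list[str], allow_network: bool = False,
                  retries: int = 2, timeout: float = 30.0):
    """Fetch protein sequences from UniProt by accession.

    Network access is opt-in: with ``allow_network=False`` (the default) any
    non-empty request raises :class:`OfflineError`.  Returns
    ``(records, failures)``; unresolvable ids are reported in ``failures`` as
    ``(id, reason)``, never silently dropped.
    """
    if not ids:
        return [], []
    if not allow_network:
        raise OfflineError(
            "fetch_uniprot called offline; pass allow_network=True to enable"
        )
    import urllib.error
    import urllib.request

    records, failures = [], []
    for acc in ids:
        url = _UNIPROT_URL.format(acc=re.sub(r"[^A-Za-z0-9_.-]", "", acc))
        last_err = None
        for _ in range(retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=timeout) as resp:
                    text = resp.read().decode()
                break
            except (urllib.error.URLError, OSError) as err:  # retry then report
                last_err = err
                text = None
        if not text:
            failures.append((acc, f"fetch failed: {last_err}"))
            continue
        parsed = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not parsed:
            failures.append((acc, "no sequence returned"))
            continue
        rec = parsed[0]
        records.append(SequenceRecord(id=acc, seq=str(rec.seq),
                                      description=rec.description))
    return records, failures
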