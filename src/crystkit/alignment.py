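"""Global alignment, identity/dissimilarity matrices, progressive multiple
alignment, codon threading, and conservation-logo information content.

The pairwise aligner is an explicit Needleman–Wunsch/Gotoh implementation with
affine gaps (a gap of length L costs ``gap_open + gap_extend * (L - 1)``) and
a deterministic traceback (diagonal > up > left).  Percent identity is, by
default, identities over mutually ungapped columns; dissimilarity is
``100 - PID``.  The progressive multiple aligner follows a guide tree (UPGMA
on the pairwise dissimilarity matrix by default) with profile–profile
alignment; it is a faithful re-implementation in spirit of Clustal-style
progressive alignment, not a clone of any particular tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import DuplicateIdError
from .seq_core import SequenceRecord

NEG_INF = float("-inf")

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        mat = substitution_matrices.load("BLOSUM62")
        _BLOSUM62 = {
            (a, b): float(mat[a][b])
            for a in mat.alphabet
            for b in mat.alphabet
        }
    return _BLOSUM62


@dataclass(frozen=True)
class PairwiseAlignment:
    ids: tuple[str, str]
    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    mutually_ungapped_columns: int


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(len(r) for r in self.rows)) > 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise dissimilarities or distances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("matrix has negative entries")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        labels, values = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            values.append([float(x) for x in parts[1 : n + 1]])
        return cls(labels=labels, values=np.array(values))


def nw_align(
    a: str,
    b: str,
    matrix: dict | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    ids: tuple[str, str] = ("a", "b"),
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap costs (Gotoh algorithm).

    A gap of length L costs ``gap_open + gap_extend * (L - 1)``; setting
    ``gap_extend == gap_open`` recovers linear gap costs.  Traceback is
    deterministic with tie-break diagonal > up (gap in ``b``) > left.
    """
    if not a or not b:
        raise ValueError("nw_align requires non-empty sequences")
    sub = matrix if matrix is not None else blosum62()
    n, m = len(a), len(b)
    # DP matrices: M match/mismatch, X gap in b (consumes a), Y gap in a.
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * (j - 1))
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, b[j - 1])]
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend,
                        Xi[j - 1] - gap_open)
    score = max(M[n][m], X[n][m], Y[n][m])
    # Traceback, preferring diagonal, then up, then left at every step.
    out_a, out_b = [], []
    i, j = n, m
    state = "M" if M[n][m] == score else ("X" if X[n][m] == score else "Y")
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sub[(a[i - 1], b[j - 1])]
            prev = M[i][j] - s
            if M[i - 1][j - 1] == prev:
                state = "M"
            elif X[i - 1][j - 1] == prev:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X" or (state == "M" and j == 0):
            out_a.append(a[i - 1])
            out_b.append("-")
            if state == "X":
                cur = X[i][j]
                if M[i - 1][j] - gap_open == cur:
                    state = "M"
                elif X[i - 1][j] - gap_extend == cur:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            if state == "Y":
                cur = Y[i][j]
                if M[i][j - 1] - gap_open == cur:
                    state = "M"
                elif Y[i][j - 1] - gap_extend == cur:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    identities, shared = _identity_counts(aligned_a, aligned_b)
    return PairwiseAlignment(
        ids=ids,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identities=identities,
        mutually_ungapped_columns=shared,
    )


def _identity_counts(ra: str, rb: str) -> tuple[int, int]:
    identities = shared = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            shared += 1
            if x == y:
                identities += 1
    return identities, shared


def percent_identity(aln: PairwiseAlignment, definition: str = "shared") -> float:
    """Percent identity of a pairwise alignment.

    ``definition``: ``"shared"`` (identities over mutually ungapped columns,
    default), ``"alignment_length"``, or ``"shorter"`` (over the shorter
    de-gapped sequence).
    """
    if definition == "shared":
        denom = aln.mutually_ungapped_columns
    elif definition == "alignment_length":
        denom = len(aln.aligned_a)
    elif definition == "shorter":
        denom = min(len(aln.aligned_a.replace("-", "")),
                    len(aln.aligned_b.replace("-", "")))
    else:
        raise ValueError(f"unknown PID definition {definition!r}")
    if denom == 0:
        import warnings

        warnings.warn("no mutually ungapped columns; PID defined as 0",
                      stacklevel=2)
        return 0.0
    return 100.0 * aln.identities / denom


def dissimilarity_matrix(
    seqs: list[SequenceRecord],
    matrix: dict | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    definition: str = "shared",
) -> DistanceMatrix:
    """All-vs-all percent-dissimilarity (100 - PID) from global alignments."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise DuplicateIdError([l for l in labels if labels.count(l) > 1])
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = nw_align(seqs[i].seq, seqs[j].seq, matrix=matrix,
                           gap_open=gap_open, gap_extend=gap_extend,
                           ids=(labels[i], labels[j]))
            D[i, j] = D[j, i] = 100.0 - percent_identity(aln, definition)
    return DistanceMatrix(labels=labels, values=D)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile_from_msa(rows: list[str], alphabet_scores: dict) -> list[dict]:
    cols = []
    for j in range(len(rows[0])):
        counts: dict[str, float] = {}
        for row in rows:
            counts[row[j]] = counts.get(row[j], 0) + 1
        total = len(rows)
        cols.append({k: v / total for k, v in counts.items()})
    return cols


def _col_score(ca: dict, cb: dict, sub: dict) -> float:
    s = 0.0
    for x, fx in ca.items():
        if x == "-":
            continue
        for y, fy in cb.items():
            if y == "-":
                continue
            s += fx * fy * sub[(x, y)]
    return s


def _align_profiles(rows_a, rows_b, sub, gap_open, gap_extend):
    pa = _profile_from_msa(rows_a, sub)
    pb = _profile_from_msa(rows_b, sub)
    n, m = len(pa), len(pb)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _col_score(pa[i - 1], pb[j - 1], sub)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    i, j = n, m
    score = max(M[n][m], X[n][m], Y[n][m])
    state = "M" if M[n][m] == score else ("X" if X[n][m] == score else "Y")
    ops = []  # 'D' consume both, 'A' consume a only, 'B' consume b only
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            ops.append("D")
            s = _col_score(pa[i - 1], pb[j - 1], sub)
            prev = M[i][j] - s
            if M[i - 1][j - 1] == prev:
                state = "M"
            elif X[i - 1][j - 1] == prev:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X" or (state == "M" and j == 0):
            ops.append("A")
            if state == "X":
                cur = X[i][j]
                if M[i - 1][j] - gap_open == cur:
                    state = "M"
                elif X[i - 1][j] - gap_extend == cur:
                    state = "X"
                else:
                    state = "Y"
            i -= 1
        else:
            ops.append("B")
            if state == "Y":
                cur = Y[i][j]
                if M[i][j - 1] - gap_open == cur:
                    state = "M"
                elif Y[i][j - 1] - gap_extend == cur:
                    state = "Y"
                else:
                    state = "X"
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "A"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("D", "B"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_msa(
    seqs: list[SequenceRecord],
    guide=None,
    matrix: dict | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Msa:
    """Guide-tree progressive multiple alignment.

    ``guide`` is a merge order as produced by UPGMA/ward clustering (a list of
    index pairs into a growing cluster list) or ``None``, in which case a
    UPGMA guide tree is built from the pairwise dissimilarity matrix.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    sub = matrix if matrix is not None else blosum62()
    if len(seqs) == 2:
        aln = nw_align(seqs[0].seq, seqs[1].seq, matrix=sub, gap_open=gap_open,
                       gap_extend=gap_extend, ids=(seqs[0].id, seqs[1].id))
        return Msa(ids=[seqs[0].id, seqs[1].id],
                   rows=[aln.aligned_a, aln.aligned_b])
    if guide is None:
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        D = dissimilarity_matrix(seqs, matrix=sub, gap_open=gap_open,
                                 gap_extend=gap_extend)
        Z = linkage(squareform(D.values, checks=False), method="average")
        merge_order = [(int(a), int(b)) for a, b, _, _ in Z]
    else:
        merge_order = list(guide)
    # Clusters indexed 0..n-1 for leaves, then one per merge.
    clusters: list[tuple[list[str], list[str]] | None] = [
        ([s.id], [s.seq]) for s in seqs
    ]
    for a, b in merge_order:
        ids_a, rows_a = clusters[a]
        ids_b, rows_b = clusters[b]
        new_a, new_b = _align_profiles(rows_a, rows_b, sub, gap_open, gap_extend)
        clusters.append((ids_a + ids_b, new_a + new_b))
    ids, rows = clusters[-1]
    # Restore the input sequence order.
    order = {sid: k for k, sid in enumerate(ids)}
    wanted = [s.id for s in seqs]
    if set(wanted) != set(ids):
        raise ValueError("guide tree labels do not match sequence ids")
    return Msa(ids=wanted, rows=[rows[order[sid]] for sid in wanted])


def codon_thread(protein_msa: Msa, cds: dict[str, str]) -> Msa:
    """Back-thread coding sequences through a protein alignment.

    Each amino-acid column becomes one codon column; alignment gaps become
    ``---``.  Every CDS must be exactly 3x its protein's ungapped length
    (stop codon stripped).
    """
    rows = []
    for sid, row in zip(protein_msa.ids, protein_msa.rows):
        if sid not in cds:
            raise ValueError(f"no CDS supplied for {sid}")
        nt = cds[sid].upper()
        if nt.endswith(("TAA", "TAG", "TGA")) and len(nt) == 3 * (
            len(row.replace("-", "")) + 1
        ):
            nt = nt[:-3]
        expected = 3 * len(row.replace("-", ""))
        if len(nt) != expected:
            raise ValueError(
                f"{sid}: CDS length {len(nt)} != expected {expected}"
            )
        out = []
        k = 0
        for aa in row:
            if aa == "-":
                out.append("---")
            else:
                out.append(nt[k : k + 3])
                k += 3
        rows.append("".join(out))
    return Msa(ids=list(protein_msa.ids), rows=rows)


@dataclass(frozen=True)
class LogoColumn:
    information: float  # bits
    letter_heights: dict[str, float]
    gap_fraction: float
    flagged: bool


def conservation_logo(msa: Msa, gap_flag_threshold: float = 0.5) -> list[LogoColumn]:
    """Per-column information content of a protein MSA.

    Information = log2(20) - Shannon entropy of the column's residue
    frequencies, with gaps excluded from the frequency normalisation.
    Columns with more than ``gap_flag_threshold`` gap fraction are flagged;
    all-gap columns carry zero information.  Letter height = frequency x
    information (frequency-based, no small-sample correction).
    """
    if len(msa.rows) < 2:
        raise ValueError("conservation logo requires >= 2 rows")
    max_info = math.log2(20)
    out = []
    for j in range(msa.column_count):
        col = msa.column(j)
        residues = [c for c in col if c != "-"]
        gap_fraction = 1 - len(residues) / len(col)
        if not residues:
            out.append(LogoColumn(0.0, {}, 1.0, True))
            continue
        freqs: dict[str, float] = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0) + 1
        total = len(residues)
        freqs = {c: n / total for c, n in freqs.items()}
        entropy = -sum(f * math.log2(f) for f in freqs.values())
        info = max(0.0, max_info - entropy)
        out.append(LogoColumn(
            information=info,
            letter_heights={c: f * info for c, f in freqs.items()},
            gap_fraction=gap_fraction,
            flagged=gap_fraction > gap_flag_threshold,
        ))
    return out
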