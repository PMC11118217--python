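"""Generators for synthetic inputs with known ground truth.

Every stage of the analysis is testable offline against these generators:
protein families with controlled Cys/Met composition evolved down a random
binary tree (optionally carrying an Asp-Cys repeat motif), matching coding
sequences by random synonymous codon choice, additive distance matrices from
random trees (the Neighbor-Joining recovery oracle), and toy atomic
structures whose solvent-accessible surface areas are known analytically or
by construction (isolated spheres, sphere pairs, and cysteines buried inside
carbon shells).

The substitution process is uniform over the target composition — adequate
for exercising alignment and clustering, but not a model of molecular
evolution.  All generators are deterministic under a fixed seed and emit a
truth object alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .alignment import DistanceMatrix
from .seq_core import SequenceRecord
from .structure_exposure import Atom, StructureModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SeqGenSpec:
    seed: int
    n_sequences: int = 20
    length_mean: float = 174.0
    length_sd: float = 5.0
    length_bounds: tuple[int, int] = (80, 200)
    target_cys_fraction: float = 0.04
    target_met_fraction: float = 0.03
    motif: tuple[str, int] | None = None  # (pattern, 0-based insert position)
    mutation_rate: float = 0.02  # per site per branch
    indel_rate: float = 0.0  # per branch
    indel_size: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        pc, pm = self.target_cys_fraction, self.target_met_fraction
        if not (0 <= pc <= 1 and 0 <= pm <= 1 and pc + pm < 1):
            raise ValueError(
                f"infeasible composition targets: Cys {pc}, Met {pm}"
            )


@dataclass
class FamilyTruth:
    ancestor: str
    tree_newick: str
    events: list[dict] = field(default_factory=list)


def _background_probs(spec: SeqGenSpec) -> np.ndarray:
    probs = np.full(20, (1 - spec.target_cys_fraction - spec.target_met_fraction) / 18)
    probs[AMINO_ACIDS.index("C")] = spec.target_cys_fraction
    probs[AMINO_ACIDS.index("M")] = spec.target_met_fraction
    return probs


def _random_topology(n: int, rng) -> TreeNode:
    nodes = [TreeNode(name=f"SEQ{i:03d}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(name=None)
        parent.append(a)
        parent.append(b)
        nodes.append(parent)
    return nodes[0]


def gen_family(spec: SeqGenSpec):
    """Evolve a protein family down a random binary tree.

    Returns ``(records, truth)``.  Each branch applies per-site substitutions
    (probability ``mutation_rate``, replacements drawn from the target
    composition so expected composition is preserved) and, with probability
    ``indel_rate``, one small insertion or deletion placed on a 10-residue
    block boundary, keeping domain-like blocks intact.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _background_probs(spec)
    lo, hi = spec.length_bounds
    length = int(np.clip(round(rng.normal(spec.length_mean, spec.length_sd)),
                         lo, hi))
    # Exact target counts in the ancestor (the family's composition tracks the
    # ancestor closely, so an i.i.d. draw would be too noisy to hit targets).
    n_cys = round(length * spec.target_cys_fraction)
    n_met = round(length * spec.target_met_fraction)
    others = [aa for aa in AMINO_ACIDS if aa not in "CM"]
    pool = (["C"] * n_cys + ["M"] * n_met
            + list(rng.choice(others, size=length - n_cys - n_met)))
    ancestor = "".join(rng.permutation(pool))
    if spec.motif is not None:
        pattern, pos = spec.motif
        if pos + len(pattern) > length:
            raise ValueError("motif does not fit in ancestor")
        ancestor = ancestor[:pos] + pattern + ancestor[pos + len(pattern):]
    tree = _random_topology(spec.n_sequences, rng)
    events: list[dict] = []

    def evolve(seq: str, node: TreeNode) -> None:
        for child in node.children:
            s = list(seq)
            hits = np.where(rng.random(len(s)) < spec.mutation_rate)[0]
            for site in hits:
                s[site] = rng.choice(list(AMINO_ACIDS), p=probs)
            child_seq = "".join(s)
            if spec.indel_rate and rng.random() < spec.indel_rate:
                boundaries = list(range(10, max(10, len(child_seq) - 10), 10))
                if boundaries:
                    at = int(rng.choice(boundaries))
                    if rng.random() < 0.5 and len(child_seq) > lo + spec.indel_size:
                        child_seq = child_seq[:at] + child_seq[at + spec.indel_size:]
                        events.append({"kind": "del", "at": at,
                                       "size": spec.indel_size})
                    else:
                        ins = "".join(rng.choice(list(AMINO_ACIDS),
                                                 size=spec.indel_size, p=probs))
                        child_seq = child_seq[:at] + ins + child_seq[at:]
                        events.append({"kind": "ins", "at": at,
                                       "size": spec.indel_size})
            if child.is_tip():
                child.seq = child_seq
            else:
                evolve(child_seq, child)

    if tree.is_tip():
        tree.seq = ancestor
    else:
        evolve(ancestor, tree)
    records = []
    for tip in sorted(tree.tips(), key=lambda t: t.name):
        records.append(SequenceRecord(id=tip.name, seq=tip.seq,
                                      organism="synthetic", mature=False))
    truth = FamilyTruth(ancestor=ancestor,
                        tree_newick=str(tree).strip(),
                        events=events)
    return records, truth


_CODON_TABLE: dict[str, list[str]] | None = None


def _codons_by_aa() -> dict[str, list[str]]:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        table: dict[str, list[str]] = {}
        for codon, aa in sorted(fwd.items()):
            table.setdefault(aa, []).append(codon)
        _CODON_TABLE = table
    return _CODON_TABLE


def gen_cds_for(records: list[SequenceRecord], seed: int) -> dict[str, str]:
    """Random synonymous coding sequence for each protein record.

    Codons are drawn uniformly among the synonymous codons of the standard
    genetic code; translation of the output recovers the input protein.
    """
    rng = np.random.default_rng(seed)
    table = _codons_by_aa()
    out = {}
    for rec in records:
        codons = []
        for aa in rec.seq:
            if aa not in table:
                raise ValueError(f"{rec.id}: no codon for residue {aa!r}")
            codons.append(table[aa][rng.integers(len(table[aa]))])
        out[rec.id] = "".join(codons)
    return out


def gen_additive_matrix(n_leaves: int, seed: int,
                        length_range: tuple[float, float] = (0.01, 1.0)):
    """Random tree with uniform branch lengths and its path-length matrix.

    The matrix is additive by construction, so Neighbor-Joining must recover
    the topology and branch lengths exactly.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(seed)
    tree = _random_topology(n_leaves, rng)
    lo, hi = length_range
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(lo, hi))
    labels = sorted(t.name for t in tree.tips())
    n = len(labels)
    D = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            d = tips[labels[i]].distance(tips[labels[j]])
            D[i, j] = D[j, i] = d
    return tree, DistanceMatrix(labels=labels, values=D)


@dataclass
class StructGenSpec:
    kind: str  # single_atom | sphere_pair | shell_buried_cys | helix_peptide
    seed: int = 0
    element: str = "C"
    separation: float = 3.0  # sphere_pair centre distance, Å
    buried: bool = True  # shell_buried_cys
    shell_radius: float = 4.0  # Å
    shell_atoms: int = 300
    n_residues: int = 12  # helix_peptide


def _shell_coords(center: np.ndarray, radius: float, count: int) -> np.ndarray:
    from .structure_exposure import golden_spiral_points

    return center + radius * golden_spiral_points(count)


def gen_structure(spec: StructGenSpec):
    """Toy structures with known SASA ground truth.

    * ``single_atom``: one atom; analytic SASA ``4π (r + probe)²``.
    * ``sphere_pair``: two identical atoms at ``separation``; analytic SASA
      by the spherical-cap formula.
    * ``shell_buried_cys``: one Cys SG atom, optionally enclosed by a dense
      carbon shell (truth label buried/exposed).
    * ``helix_peptide``: CA trace of an ideal α-helix (ordering/monotonicity
      tests).

    Returns ``(StructureModel, truth_dict)``.
    """
    if spec.kind == "single_atom":
        atoms = [Atom(1, spec.element, spec.element, "UNK", 1, "A", (0, 0, 0))]
        return StructureModel(atoms=atoms), {"kind": "single_atom"}
    if spec.kind == "sphere_pair":
        if spec.separation <= 0:
            raise ValueError("separation must be positive")
        atoms = [
            Atom(1, spec.element, spec.element, "UNK", 1, "A", (0, 0, 0)),
            Atom(2, spec.element, spec.element, "UNK", 2, "A",
                 (spec.separation, 0, 0)),
        ]
        return StructureModel(atoms=atoms), {
            "kind": "sphere_pair", "separation": spec.separation,
        }
    if spec.kind == "shell_buried_cys":
        atoms = [Atom(1, "S", "SG", "CYS", 1, "A", (0, 0, 0))]
        if spec.buried:
            serial = 2
            for xyz in _shell_coords(np.zeros(3), spec.shell_radius,
                                     spec.shell_atoms):
                atoms.append(Atom(serial, "C", "C", "GLY", 100 + serial, "A",
                                  tuple(xyz)))
                serial += 1
        return StructureModel(atoms=atoms), {
            "kind": "shell_buried_cys", "buried": spec.buried,
        }
    if spec.kind == "helix_peptide":
        atoms = []
        for i in range(spec.n_residues):
            theta = math.radians(100.0) * i
            atoms.append(Atom(i + 1, "C", "CA", "ALA", i + 1, "A",
                              (2.3 * math.cos(theta), 2.3 * math.sin(theta),
                               1.5 * i)))
        return StructureModel(atoms=atoms), {"kind": "helix_peptide",
                                             "n_residues": spec.n_residues}
    raise ValueError(f"unknown structure kind {spec.kind!r}")


def sphere_pair_analytic_sasa(r_vdw: float, probe: float,
                              separation: float) -> float:
    """Exact per-sphere SASA of two identical overlapping spheres.

    For extended radius R = r_vdw + probe and centre distance d < 2R, each
    sphere loses a cap of height h = R - d/2; exposed area per sphere is
    ``4πR² - 2πRh``.  Non-overlapping spheres are unoccluded.
    """
    R = r_vdw + probe
    if separation >= 2 * R:
        return 4 * math.pi * R * R
    h = R - separation / 2
    return 4 * math.pi * R * R - 2 * math.pi * R * h


def gen_exposure_cohort(n: int, seed: int):
    """Cohort of two-domain toy structures with planted exposure classes.

    Each structure has one Cys in the N-terminal half (residue 10) and one in
    the C-terminal half (residue 110), each either buried inside a carbon
    shell or fully exposed, plus an always-buried control Cys (residue 50).
    The planted class cycles through NTD, CTD, both, neither.  Returns a list
    of dicts with keys id, model, truth_class, boundary, control_residue.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    classes = ["NTD", "CTD", "both", "neither"]
    cohort = []
    for k in range(n):
        cls = classes[k % 4]
        ntd_exposed = cls in ("NTD", "both")
        ctd_exposed = cls in ("CTD", "both")
        atoms = []
        serial = 1

        def add_cys(resnum, center, exposed):
            nonlocal serial
            atoms.append(Atom(serial, "S", "SG", "CYS", resnum, "A",
                              tuple(center)))
            serial += 1
            if not exposed:
                for xyz in _shell_coords(np.asarray(center, float), 4.0, 300):
                    atoms.append(Atom(serial, "C", "C", "GLY", 1000 + serial,
                                      "A", tuple(xyz)))
                    serial += 1

        add_cys(10, (0.0, 0.0, 0.0), ntd_exposed)
        add_cys(50, (30.0, 0.0, 0.0), False)  # buried control
        add_cys(110, (60.0, 0.0, 0.0), ctd_exposed)
        # A few inert far-away atoms so structures are not identical.
        for _ in range(3):
            xyz = rng.uniform(90, 120, size=3)
            atoms.append(Atom(serial, "C", "C", "GLY", 2000 + serial, "A",
                              tuple(xyz)))
            serial += 1
        cohort.append({
            "id": f"STR{k:03d}",
            "model": StructureModel(atoms=atoms),
            "truth_class": cls,
            "boundary": 60,
            "control_residue": 50,
        })
    return cohort
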