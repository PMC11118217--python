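"""Structure reading, Shrake–Rupley solvent-accessible surface area, and
per-domain cysteine exposure classification.

The exposure statistic mirrors the lens-crystallin analysis: for each protein,
sum the SASA of all Cys residues in the N-terminal domain (residue number at
or below the interdomain boundary) and in the C-terminal domain separately,
then compare each domain sum to a baseline built from a conserved buried
control Cys (e.g. C83 of human γS) across the structure set.  A domain counts
as solvent-exposed when its combined Cys SASA exceeds
``baseline mean + multiplier × SD`` (multiplier 1 by default).

SASA uses the Shrake–Rupley algorithm with a deterministic golden-spiral test
point lattice (960 points per atom, probe 1.4 Å by default).  Residue
numbering follows the UniProt convention, counting Met1 as the first residue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import StructureError

#: Default van der Waals radii (Å), swappable per call.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


@dataclass(frozen=True)
class Atom:
    serial: int
    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    xyz: tuple[float, float, float]


@dataclass
class StructureModel:
    atoms: list[Atom]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("empty structure model")
        seen = set()
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.xyz):
                raise StructureError(f"atom {a.serial}: non-finite coordinates")
            if a.xyz in seen:
                raise StructureError(
                    f"atom {a.serial}: duplicate coordinates {a.xyz}"
                )
            seen.add(a.xyz)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def residue_numbers(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms})


@dataclass
class SasaResult:
    per_atom: np.ndarray  # Å², aligned with StructureModel.atoms
    per_residue: dict[tuple[str, int], float]  # (chain, residue_number) -> Å²
    probe_radius: float
    points_per_atom: int
    radii_set: str = "default"

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def read_structure(path, format: str | None = None,
                   renumber_offset: int = 0) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (via gemmi).

    Only the first model of multi-model (NMR) files is used; alternate
    locations resolve to the highest-occupancy conformer; waters are dropped.
    ``renumber_offset`` is added to author residue numbers to restore UniProt
    numbering when the deposited numbering differs.
    """
    import gemmi

    path = str(path)
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    if format == "pdb":
        st = gemmi.read_pdb(path)
    elif format == "mmcif":
        st = gemmi.read_structure(path)
    else:
        raise ValueError(f"unknown structure format {format!r}")
    st.remove_waters()
    st.remove_alternative_conformations()  # keeps highest occupancy
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    atoms = []
    serial = 0
    for chain in model:
        for res in chain:
            for at in res:
                serial += 1
                el = at.element.name.upper() if at.element else ""
                if not el:
                    raise StructureError(
                        f"{path}: atom {at.name} has unknown element"
                    )
                atoms.append(Atom(
                    serial=serial,
                    element=el,
                    name=at.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num + renumber_offset,
                    chain=chain.name,
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                ))
    if not atoms:
        raise StructureError(f"{path}: empty model")
    return StructureModel(atoms=atoms, source=path)


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "crystkit"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != a.residue_number:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            ch.add_residue(res)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.xyz)
        at.occ = 1.0
        ch[-1].add_atom(at)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    model: StructureModel,
    probe: float = 1.4,
    points: int = 960,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Per-atom and per-residue SASA by the Shrake–Rupley method.

    Each atom's extended sphere (r_vdw + probe) carries a deterministic
    golden-spiral lattice of test points; a point is exposed if it lies
    outside every neighbouring atom's extended sphere.  Per-atom SASA is
    (exposed / total points) × 4π (r_vdw + probe)².
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if points < 92:
        raise ValueError("need at least 92 test points per atom")
    radii = radii or DEFAULT_RADII
    try:
        r = np.array([radii[a.element] for a in model.atoms])
    except KeyError as err:
        raise StructureError(f"no van der Waals radius for element {err}") from None
    xyz = model.coords()
    n = len(model.atoms)
    ext = r + probe
    sphere = golden_spiral_points(points)
    per_atom = np.zeros(n)
    for i in range(n):
        test = xyz[i] + ext[i] * sphere
        # Neighbours whose extended spheres can occlude atom i's surface.
        dists = np.linalg.norm(xyz - xyz[i], axis=1)
        nbr = np.where((dists < ext + ext[i]) & (np.arange(n) != i))[0]
        exposed = np.ones(points, dtype=bool)
        for j in nbr:
            d2 = np.sum((test - xyz[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
            if not exposed.any():
                break
        per_atom[i] = exposed.sum() / points * 4 * math.pi * ext[i] ** 2
    per_residue: dict[tuple[str, int], float] = {}
    for a, s in zip(model.atoms, per_atom):
        key = (a.chain, a.residue_number)
        per_residue[key] = per_residue.get(key, 0.0) + float(s)
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe, points_per_atom=points)


@dataclass(frozen=True)
class ExposureReport:
    protein_id: str
    boundary: int
    ntd_cys_sasa: float
    ctd_cys_sasa: float
    control_sasa: float | None
    baseline_mean: float | None
    baseline_sd: float | None
    exposure_class: str | None


def domain_cys_sasa(
    model: StructureModel,
    sasa: SasaResult,
    boundary: int,
    side_chain_only: bool = False,
) -> tuple[float, float]:
    """Combined Cys SASA for the N-terminal (residue number <= boundary) and
    C-terminal (> boundary) domains.

    With ``side_chain_only`` the backbone atoms (N, CA, C, O) are excluded.
    Returns (0, 0) with a warning when the structure has no cysteines.
    """
    res_numbers = model.residue_numbers()
    if not res_numbers[0] <= boundary <= res_numbers[-1]:
        raise ValueError(
            f"boundary {boundary} outside residue range "
            f"{res_numbers[0]}..{res_numbers[-1]}"
        )
    backbone = {"N", "CA", "C", "O"}
    ntd = ctd = 0.0
    seen_cys = False
    for a, s in zip(model.atoms, sasa.per_atom):
        if a.residue_name != "CYS":
            continue
        seen_cys = True
        if side_chain_only and a.name in backbone:
            continue
        if a.residue_number <= boundary:
            ntd += float(s)
        else:
            ctd += float(s)
    if not seen_cys:
        warnings.warn(f"{model.source}: no Cys residues", stacklevel=2)
    return ntd, ctd


def buried_control_baseline(controls: list[tuple[str, float | None]]):
    """Mean and sample SD of control buried-Cys SASA across structures.

    Entries with a missing control (``None``) are excluded and reported.
    Returns ``(mean, sd, excluded_ids)``; at least two usable controls are
    required for the SD to be defined.
    """
    usable = [(pid, v) for pid, v in controls if v is not None]
    excluded = [pid for pid, v in controls if v is None]
    if len(usable) < 2:
        raise ValueError("buried-control baseline requires >= 2 structures")
    values = np.array([v for _, v in usable])
    return float(values.mean()), float(values.std(ddof=1)), excluded


def classify_exposure(
    ntd_sum: float,
    ctd_sum: float,
    baseline_mean: float,
    baseline_sd: float,
    sd_multiplier: float = 1.0,
) -> str:
    """Exposure class from domain Cys SASA sums vs the buried-control
    threshold (strictly greater than mean + multiplier × SD)."""
    for v in (ntd_sum, ctd_sum, baseline_mean, baseline_sd):
        if v < 0:
            raise ValueError("negative SASA input")
    threshold = baseline_mean + sd_multiplier * baseline_sd
    ntd_exposed = ntd_sum > threshold
    ctd_exposed = ctd_sum > threshold
    if ntd_exposed and ctd_exposed:
        return "both"
    if ntd_exposed:
        return "NTD"
    if ctd_exposed:
        return "CTD"
    return "neither"


def control_cys_sasa(model: StructureModel, sasa: SasaResult,
                     control_residue: int | None) -> float | None:
    """Whole-residue SASA of the designated control Cys, or None if absent."""
    if control_residue is None:
        return None
    total = None
    for a, s in zip(model.atoms, sasa.per_atom):
        if a.residue_number == control_residue and a.residue_name == "CYS":
            total = (total or 0.0) + float(s)
    return total


def exposure_report(
    protein_id: str,
    model: StructureModel,
    boundary: int,
    control_residue: int | None,
    baseline: tuple[float, float] | None = None,
    probe: float = 1.4,
    points: int = 960,
    sd_multiplier: float = 1.0,
    side_chain_only: bool = False,
) -> ExposureReport:
    """Full per-protein exposure workflow: SASA, domain sums, classification
    (classification only when a baseline is supplied)."""
    sasa = shrake_rupley(model, probe=probe, points=points)
    ntd, ctd = domain_cys_sasa(model, sasa, boundary,
                               side_chain_only=side_chain_only)
    control = control_cys_sasa(model, sasa, control_residue)
    if baseline is None:
        return ExposureReport(protein_id, boundary, ntd, ctd, control,
                              None, None, None)
    mean, sd = baseline
    return ExposureReport(
        protein_id, boundary, ntd, ctd, control, mean, sd,
        classify_exposure(ntd, ctd, mean, sd, sd_multiplier=sd_multiplier),
    )
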