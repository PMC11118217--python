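import math

import numpy as np
import pytest

from oracles import monte_carlo_sasa

from crystkit.errors import StructureError
from crystkit.structure_exposure import (
    Atom,
    StructureModel,
    buried_control_baseline,
    classify_exposure,
    control_cys_sasa,
    domain_cys_sasa,
    read_structure,
    shrake_rupley,
    write_pdb,
)
from crystkit.synthetic_data import (
    StructGenSpec,
    gen_structure,
    sphere_pair_analytic_sasa,
)


def random_cluster(rng, n_atoms, box=8.0):
    elements = ["C", "N", "O", "S"]
    atoms = []
    for i in range(n_atoms):
        atoms.append(Atom(i + 1, elements[int(rng.integers(4))], "X", "UNK",
                          i + 1, "A", tuple(rng.uniform(0, box, size=3))))
    return StructureModel(atoms=atoms)


class TestReadWrite:
    def test_single_atom_pdb(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000"
            "  1.00  0.00           C\nEND\n")
        model = read_structure(p)
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz == pytest.approx((1.0, 2.0, 3.0))
        assert model.atoms[0].element == "C"

    def test_multi_model_uses_first(self, tmp_path):
        body = ("MODEL     {m}\n"
                "ATOM      1  CA  GLY A   1      {x}   0.000   0.000"
                "  1.00  0.00           C\nENDMDL\n")
        p = tmp_path / "nmr.pdb"
        p.write_text("".join(body.format(m=m, x=f"{m:5.3f}")
                             for m in (1, 2, 3)) + "END\n")
        model = read_structure(p)
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz[0] == pytest.approx(1.0)

    def test_round_trip(self, tmp_path):
        model, _ = gen_structure(StructGenSpec(kind="helix_peptide",
                                               n_residues=6))
        p = tmp_path / "helix.pdb"
        write_pdb(model, p)
        back = read_structure(p)
        assert len(back.atoms) == len(model.atoms)
        for a, b in zip(model.atoms, back.atoms):
            assert b.xyz == pytest.approx(a.xyz, abs=1e-3)
            assert (b.element, b.residue_number) == (a.element,
                                                    a.residue_number)

    def test_duplicate_coordinates_rejected(self):
        atoms = [Atom(1, "C", "C", "UNK", 1, "A", (0, 0, 0)),
                 Atom(2, "C", "C", "UNK", 2, "A", (0, 0, 0))]
        with pytest.raises(StructureError, match="duplicate"):
            StructureModel(atoms=atoms)


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        model, _ = gen_structure(StructGenSpec(kind="single_atom"))
        sasa = shrake_rupley(model)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert sasa.total == pytest.approx(exact, rel=5e-3)

    def test_distant_spheres_unoccluded(self):
        model, _ = gen_structure(StructGenSpec(kind="sphere_pair",
                                               separation=10.0))
        sasa = shrake_rupley(model)
        exact = 4 * math.pi * 3.1 ** 2
        assert sasa.per_atom == pytest.approx([exact, exact], rel=5e-3)

    @pytest.mark.parametrize("sep", [2.0, 3.0, 4.5])
    def test_two_sphere_analytic_solution(self, sep):
        model, _ = gen_structure(StructGenSpec(kind="sphere_pair",
                                               separation=sep))
        sasa = shrake_rupley(model, points=960)
        exact = sphere_pair_analytic_sasa(1.70, 1.4, sep)
        for got in sasa.per_atom:
            assert got == pytest.approx(exact, rel=0.01)

    def test_point_count_convergence(self, rng):
        model = random_cluster(rng, 30)
        a = shrake_rupley(model, points=960).total
        b = shrake_rupley(model, points=4000).total
        assert abs(a - b) / b < 0.01

    def test_matches_monte_carlo_oracle(self, rng):
        from crystkit.structure_exposure import DEFAULT_RADII

        model = random_cluster(rng, 50)
        mine = shrake_rupley(model, points=2000).total
        radii = [DEFAULT_RADII[a.element] for a in model.atoms]
        mc = monte_carlo_sasa(model.coords(), radii, 1.4, n_samples=4000,
                              seed=7)
        assert mine == pytest.approx(mc, rel=0.02)

    def test_matches_biotite_reference(self):
        """Independent cross-check against biotite's Shrake-Rupley."""
        import biotite.structure as struc

        rng = np.random.default_rng(4)
        model = random_cluster(rng, 25)
        arr = struc.AtomArray(len(model.atoms))
        for i, a in enumerate(model.atoms):
            arr.coord[i] = a.xyz
            arr.element[i] = a.element
            arr.res_id[i] = a.residue_number
            arr.atom_name[i] = a.name
            arr.res_name[i] = a.residue_name
            arr.chain_id[i] = a.chain
        from crystkit.structure_exposure import DEFAULT_RADII

        ref = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                         vdw_radii="Single",
                         atom_filter=np.ones(len(model.atoms), bool))
        # biotite uses its own radii set; compare with matched radii instead.
        mine = shrake_rupley(model, points=1000,
                             radii={"C": 1.70, "N": 1.55, "O": 1.52,
                                    "S": 1.80}).total
        assert mine == pytest.approx(float(ref.sum()), rel=0.05)

    def test_occlusion_monotone_under_added_shells(self):
        from crystkit.synthetic_data import _shell_coords

        core = [Atom(1, "S", "SG", "CYS", 1, "A", (0, 0, 0))]
        atoms = list(core)
        serial = 2
        for radius, count in ((6.0, 60), (5.0, 80)):
            for xyz in _shell_coords(np.zeros(3), radius, count):
                atoms.append(Atom(serial, "C", "C", "GLY", serial, "A",
                                  tuple(xyz)))
                serial += 1
        sparse = StructureModel(atoms=core + atoms[1:61])
        dense = StructureModel(atoms=atoms)
        s_core = shrake_rupley(StructureModel(atoms=core), points=500)
        s_sparse = shrake_rupley(sparse, points=500)
        s_dense = shrake_rupley(dense, points=500)
        assert s_core.per_atom[0] >= s_sparse.per_atom[0] >= s_dense.per_atom[0]

    def test_parameter_validation(self):
        model, _ = gen_structure(StructGenSpec(kind="single_atom"))
        with pytest.raises(ValueError):
            shrake_rupley(model, probe=0)
        with pytest.raises(ValueError):
            shrake_rupley(model, points=50)
        bad = StructureModel(atoms=[Atom(1, "ZZ", "Z", "UNK", 1, "A",
                                         (0, 0, 0))])
        with pytest.raises(StructureError, match="radius"):
            shrake_rupley(bad)


class TestDomainCysSasa:
    def test_no_cys_returns_zero_with_warning(self):
        model, _ = gen_structure(StructGenSpec(kind="helix_peptide"))
        sasa = shrake_rupley(model, points=200)
        with pytest.warns(UserWarning, match="no Cys"):
            assert domain_cys_sasa(model, sasa, 6) == (0.0, 0.0)

    def test_buried_cys_in_each_half_sums_near_zero(self):
        from crystkit.synthetic_data import gen_exposure_cohort

        entry = next(c for c in gen_exposure_cohort(8, seed=0)
                     if c["truth_class"] == "neither")
        sasa = shrake_rupley(entry["model"], points=500)
        ntd, ctd = domain_cys_sasa(entry["model"], sasa, entry["boundary"])
        assert ntd == pytest.approx(0.0, abs=1.0)
        assert ctd == pytest.approx(0.0, abs=1.0)

    def test_invariant_to_atom_ordering(self, rng):
        model, _ = gen_structure(StructGenSpec(kind="shell_buried_cys",
                                               buried=False))
        atoms = list(model.atoms)
        extra = [Atom(99, "S", "SG", "CYS", 120, "A", (20.0, 0, 0))]
        fwd = StructureModel(atoms=atoms + extra)
        rev = StructureModel(atoms=extra + atoms)
        s_fwd = shrake_rupley(fwd, points=500)
        s_rev = shrake_rupley(rev, points=500)
        assert domain_cys_sasa(fwd, s_fwd, 60) == pytest.approx(
            domain_cys_sasa(rev, s_rev, 60))

    def test_boundary_out_of_range_rejected(self):
        model, _ = gen_structure(StructGenSpec(kind="helix_peptide"))
        sasa = shrake_rupley(model, points=200)
        with pytest.raises(ValueError, match="boundary"):
            domain_cys_sasa(model, sasa, 999)


class TestBaselineAndClassification:
    def test_baseline_mean_and_sd(self):
        mean, sd, excluded = buried_control_baseline([("a", 2.0), ("b", 4.0)])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(1.414, abs=5e-4)
        assert excluded == []

    def test_missing_controls_excluded_and_reported(self):
        mean, sd, excluded = buried_control_baseline(
            [("a", 2.0), ("b", None), ("c", 4.0)])
        assert excluded == ["b"]

    def test_single_structure_rejected(self):
        with pytest.raises(ValueError):
            buried_control_baseline([("a", 2.0)])

    def test_equal_controls_zero_sd(self):
        _, sd, _ = buried_control_baseline([("a", 2.0), ("b", 2.0)])
        assert sd == 0.0

    @pytest.mark.parametrize("ntd, ctd, expected", [
        (0, 0, "neither"),
        (50, 2, "NTD"),
        (2, 50, "CTD"),
        (50, 50, "both"),
    ])
    def test_threshold_logic(self, ntd, ctd, expected):
        assert classify_exposure(ntd, ctd, 3, 1) == expected

    def test_threshold_is_strict(self):
        assert classify_exposure(4.0, 0.0, 3.0, 1.0) == "neither"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_exposure(-1, 0, 3, 1)

    def test_control_residue_lookup(self):
        model, _ = gen_structure(StructGenSpec(kind="shell_buried_cys",
                                               buried=False))
        sasa = shrake_rupley(model, points=200)
        assert control_cys_sasa(model, sasa, 1) > 0
        assert control_cys_sasa(model, sasa, 77) is None
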