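"""Generators: determinism, prescribed ground truth, end-to-end pipeline."""

import dataclasses

import numpy as np
import pytest
from rdkit import Chem

from pmk import chemistry, geometry, profiles as pr, synthdata as sd
from pmk.assays import binding_from_dialysis, papp
from pmk.errors import InfeasibleTarget
from pmk.orientation import assign_group


class TestFragmentLibraries:
    def test_all_entries_parse(self, libs):
        for group in ("e3_ligands", "linkers", "poi_ligands"):
            for name, smi in libs[group].items():
                if smi == "":
                    continue
                assert Chem.MolFromSmiles(smi) is not None, name

    def test_peg3_is_nine_atom_chain(self):
        smi = sd.peg_linker(3)
        heavy = Chem.MolFromSmiles(smi).GetNumAtoms() - 2  # minus 2 dummies
        assert heavy == 9
        profile = chemistry.classify_linker_motifs(sd._cap_with_h(smi))
        assert profile.peg_monomers == 3

    def test_alkyl6_run(self):
        profile = chemistry.classify_linker_motifs(sd._cap_with_h(sd.alkyl_linker(6)))
        assert profile.alkyl_max_run == 6

    def test_cores_match_their_own_patterns(self, libs):
        for name, smi in libs["e3_ligands"].items():
            record, _ = sd.assemble_protac(
                smi, libs["linkers"]["linker_alkyl4"], libs["poi_ligands"]["poi_toluene"]
            )
            dec = chemistry.decompose(record.smiles)
            assert dec.e3_class.value == libs["e3_classes"][name]


class TestAssembly:
    def test_vhl_class_roundtrip(self, libs):
        record, _ = sd.assemble_protac(
            libs["e3_ligands"]["vhl_vh032"],
            libs["linkers"]["linker_alkyl5"],
            libs["poi_ligands"]["poi_toluene"],
            e3_class="VHL",
        )
        assert chemistry.decompose(record.smiles).e3_class is chemistry.E3Class.VHL

    def test_connected_single_molecule(self, peg3_protac):
        record, _ = peg3_protac
        assert len(Chem.GetMolFrags(Chem.MolFromSmiles(record.smiles))) == 1

    def test_empty_linker_direct_bond(self, libs):
        record, truth = sd.assemble_protac(
            libs["e3_ligands"]["crbn_thalidomide_o"], "", libs["poi_ligands"]["poi_toluene"]
        )
        dec = chemistry.decompose(record.smiles)
        assert dec.linker_smiles == "" == truth.values["linker_capped"]


class TestConformerEnsembles:
    def test_prescribed_contraction_recovered(self, peg3_protac, peg3_decomposition):
        record, _ = peg3_protac
        dec = peg3_decomposition
        targets = [(100.0, 100.0), (50.0, 80.0), (25.0, 30.0)]
        ens, truth = sd.generate_conformer_ensemble(record, dec, targets, seed=5)
        molh, xy = geometry.layout_2d(chemistry.mol_from_smiles(record.smiles))
        _, d_l, _, d_max = geometry.max_extended_distance_2d(
            xy, ens.masses, ens.domains, dec.e3_anchor, dec.poi_anchor, ens.elements
        )
        for k, (mt, lt) in enumerate(targets):
            mc = geometry.molecule_contraction(
                ens.coords[k], ens.masses, ens.domains, d_max, ens.elements
            )
            lc = geometry.linker_contraction(
                ens.coords[k], dec.e3_anchor, dec.poi_anchor, d_l
            )
            assert mc == pytest.approx(mt, abs=1e-6)
            assert lc == pytest.approx(lt, abs=1e-6)

    def test_seed_determinism(self, peg3_protac, peg3_decomposition):
        record, _ = peg3_protac
        a, _ = sd.generate_conformer_ensemble(record, peg3_decomposition, [(60.0, 70.0)], seed=9)
        b, _ = sd.generate_conformer_ensemble(record, peg3_decomposition, [(60.0, 70.0)], seed=9)
        assert np.array_equal(a.coords[0], b.coords[0])
        assert np.array_equal(a.energies, b.energies)

    def test_energy_window(self, peg3_protac, peg3_decomposition):
        record, _ = peg3_protac
        ens, _ = sd.generate_conformer_ensemble(
            record, peg3_decomposition, [(50.0, 50.0)] * 40, seed=2
        )
        assert ens.energies.min() == 0.0
        assert ens.energies.max() <= 21.0

    def test_infeasible_target(self, peg3_protac, peg3_decomposition):
        record, _ = peg3_protac
        # anchors nearly coincident but COM distance at full extension
        with pytest.raises(InfeasibleTarget):
            sd.generate_conformer_ensemble(record, peg3_decomposition, [(100.0, 0.5)], seed=1)


class TestProfiles:
    def test_noise_free_barriers_recovered(self):
        arch = sd.ProfileArchetype(depth_min=20.0, barrier_core=30.0, noise_sigma=0.0)
        plist, truth = sd.generate_profiles(arch, 1, seed=0)
        b = pr.extract_barriers(pr.normalize_profile(plist[0]))
        t = truth.values["barriers"]
        assert b.depth_min == pytest.approx(t["depth_min"], abs=0.2)
        assert b.barrier_min_to_core == pytest.approx(t["barrier_min_to_core"], abs=0.2)
        assert b.dominant_kind == "to_core"
        assert b.dominant_barrier == pytest.approx(50.0, abs=1.0)

    def test_flat_archetype(self):
        arch = sd.ProfileArchetype(depth_min=0.0, barrier_core=0.0, noise_sigma=0.0)
        plist, _ = sd.generate_profiles(arch, 1, seed=0)
        b = pr.extract_barriers(pr.normalize_profile(plist[0]))
        assert b.depth_min == 0.0 and b.dominant_barrier == 0.0

    def test_seed_determinism(self):
        arch = sd.ProfileArchetype(noise_sigma=1.0)
        a, _ = sd.generate_profiles(arch, 3, seed=4)
        b, _ = sd.generate_profiles(arch, 3, seed=4)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.g, pb.g)

    def test_archetype_families_cluster_apart(self):
        profs, labels = [], []
        for i in range(30):
            arch = dataclasses.replace(
                sd.ARCHETYPE_INTERFACE_BINDER if i % 2 == 0 else sd.ARCHETYPE_CORE_BLOCKED,
                noise_sigma=1.0,
            )
            plist, _ = sd.generate_profiles(arch, 1, seed=300 + i)
            profs.append(pr.normalize_profile(plist[0]))
            labels.append(i % 2)
        got, _ = pr.cluster_profiles(profs, 2)
        labels = np.array(labels)
        agreement = max(np.mean(got == labels), np.mean(got != labels))
        assert agreement >= 0.95


class TestOrientationStates:
    def test_known_distribution_recovered(self):
        # feasible groups only: e.g. (2,2,2) is excluded by the spherical
        # constraint (two vectors within 60 deg of -z are < 120 deg apart)
        probs = {0: 0.25, 8: 0.25, 13: 0.25, 24: 0.25}
        states, truth = sd.generate_orientation_states(probs, 400, seed=6)
        counts = np.bincount([assign_group(s).index for s in states], minlength=27)
        for g, p in probs.items():
            # binomial 99.9% interval around p
            se = np.sqrt(p * (1 - p) / 400)
            assert abs(counts[g] / 400 - p) < 3.5 * se

    def test_states_are_geometric(self):
        states, _ = sd.generate_orientation_states({0: 0.5, 24: 0.5}, 50, seed=7)
        for s in states:
            a1, a2, a3 = s.angle_normal_e3, s.angle_normal_poi, s.angle_e3_poi
            assert abs(a1 - a2) - 1e-9 <= a3 <= min(a1 + a2, 360 - a1 - a2) + 1e-9


class TestAssayGenerators:
    def test_noise_free_fu_roundtrip(self):
        meas, truth = sd.generate_dialysis_data(0.5, noise_cv=0.0, seed=1)
        for m in meas:
            assert binding_from_dialysis(m).fu == pytest.approx(0.5, rel=1e-12)

    def test_below_lloq_scenario_flags_imputation(self):
        meas, _ = sd.generate_dialysis_data(0.002, noise_cv=0.0, seed=1, lloq=0.001)
        # fu 0.002 at 0.1 uM -> buffer 0.0002 uM, below LLOQ 0.001
        assert all(binding_from_dialysis(m).lloq_imputed for m in meas)

    def test_papp_roundtrip_under_sink(self):
        exp, truth = sd.generate_transport_data(1e-6, noise_cv=0.0, seed=2)
        est = papp(exp, donor_mode="mean").papp
        assert est == pytest.approx(truth.values["papp"], rel=0.01)

    def test_generators_are_pure(self):
        a, _ = sd.generate_transport_data(1e-6, noise_cv=0.1, seed=3)
        b, _ = sd.generate_transport_data(1e-6, noise_cv=0.1, seed=3)
        assert a.receiver_conc == b.receiver_conc


class TestEndToEnd:
    def test_cohort_pipeline(self):
        """A 56-compound cohort survives decompose -> descriptors -> profile
        barrier recovery with 100% decomposition round-trip."""
        pairs = sd.generate_cohort(56, seed=11)
        assert len(pairs) == 56
        rng = np.random.Generator(np.random.Philox(11))
        n_ok = 0
        for record, truth in pairs:
            dec = chemistry.decompose(record.smiles)
            ok = (
                dec.e3_smiles == truth.values["e3_capped"]
                and dec.linker_smiles == truth.values["linker_capped"]
                and dec.poi_smiles == truth.values["poi_capped"]
            )
            n_ok += ok
            d = chemistry.compute_2d_descriptors(record.smiles)
            assert d.mw > 0
        assert n_ok == 56
        # barrier recovery leg on the same cohort size
        recovered = 0
        for i in range(56):
            arch = sd.ProfileArchetype(
                depth_min=float(rng.uniform(8, 30)),
                z_min=float(rng.uniform(12, 18)),
                barrier_core=float(rng.uniform(10, 50)),
                well_width=float(rng.uniform(3, 5)),
                noise_sigma=1.0,
            )
            plist, truth = sd.generate_profiles(arch, 1, seed=int(rng.integers(2**31)))
            b = pr.extract_barriers(pr.normalize_profile(plist[0]))
            t = truth.values["barriers"]
            tol = max(2.0, t["max_abs_slope_interface"])
            recovered += (
                abs(b.depth_min - t["depth_min"]) <= tol
                and abs(b.barrier_min_to_core - t["barrier_min_to_core"]) <= tol
            )
        assert recovered / 56 >= 0.95
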