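"""Network construction: topology enumeration, stoichiometry, strains."""

import numpy as np
import pytest

from hogpath.network import (NetworkError, StrainError, StrainSpec,
                             TopologyConfig, apply_strain,
                             build_basic_cascade, build_network,
                             enumerate_topologies)


class TestEnumeration:
    def test_canonical_count(self):
        assert len(enumerate_topologies()) == 8

    def test_with_mixed_count(self):
        tops = enumerate_topologies(include_mixed=True)
        assert len(tops) == 12
        assert sum(t.mechanism == "mixed" for t in tops) == 4

    def test_all_distinct(self):
        tops = enumerate_topologies(include_mixed=True)
        assert len(set(tops)) == 12

    def test_no_target_means_no_components(self):
        for t in enumerate_topologies(include_mixed=True):
            if t.positive_feedback_target == "none":
                assert not t.feedback_components

    def test_invalid_configs_rejected(self):
        with pytest.raises(NetworkError):
            TopologyConfig(positive_feedback_target="none",
                           feedback_components=frozenset({"affinity"}))
        with pytest.raises(NetworkError):
            TopologyConfig(positive_feedback_target="pbs2",
                           feedback_components=frozenset())
        with pytest.raises(NetworkError):
            TopologyConfig(mechanism="telepathic")


class TestBuildNetwork:
    @pytest.mark.parametrize("topology", enumerate_topologies(include_mixed=True),
                             ids=lambda t: t.label)
    def test_stoichiometric_conservation(self, topology):
        """Every protein's conserved-total indicator is a left null vector."""
        net = build_network(topology)
        N = net.stoichiometry_matrix()
        for protein in net.conserved_totals:
            v = net.conservation_vector(protein)
            assert np.allclose(v @ N, 0.0, atol=1e-12), protein

    def test_processive_never_releases_bound_mono(self):
        net = build_network(TopologyConfig(mechanism="processive"))
        for rxn in net.reactions:
            reactant_names = {sp for sp, _ in rxn.reactants}
            if any("Hog1P" in s and "Hog1PP" not in s for s in reactant_names
                   if s.startswith("Pbs2")):
                products = {sp for sp, _ in rxn.products}
                assert "Hog1P_c" not in products, rxn.name

    def test_mixed_has_feedback_complex_with_boosted_rate(self):
        net = build_network(TopologyConfig(mechanism="mixed"))
        assert "Pbs2PPHog1P" in net.species_names
        assert "Pbs2PPHog1P_feedback" in net.species_names
        plain = [r for r in net.reactions
                 if r.name == "hog1_second_phospho_immediate"][0]
        fb = [r for r in net.reactions
              if r.name == "hog1_second_phospho_immediate_fb"][0]
        assert "k_phospho" in plain.params and "fb_catalytic" not in plain.params
        assert "k_phospho" in fb.params and "fb_catalytic" in fb.params

    def test_alternative_feedback_targets_build(self):
        for target in ("sln1_and_ste20", "ssk1_and_ste20"):
            top = TopologyConfig(mechanism="mixed",
                                 positive_feedback_target=target)
            net = build_network(top)
            N = net.stoichiometry_matrix()
            for protein in net.conserved_totals:
                assert np.allclose(net.conservation_vector(protein) @ N, 0.0)

    def test_physiological_bounds_tighten_ranges(self):
        loose = build_network(TopologyConfig())
        tight = build_network(TopologyConfig(bounds_mode="physiological"))
        p_loose = loose.parameters["kon_hog1"]
        p_tight = tight.parameters["kon_hog1"]
        assert (p_tight.upper - p_tight.lower) < (p_loose.upper - p_loose.lower)

    def test_reaction_table_and_sbml_export(self, mixed_network):
        table = mixed_network.to_table()
        assert "hog1_binding" in table
        assert len(table.strip().splitlines()) == len(mixed_network.reactions) + 1
        sbml = mixed_network.to_sbml()
        assert sbml.startswith("<?xml") and "Pbs2PPHog1P" in sbml

    def test_every_reaction_parameter_exists(self, mixed_network):
        for rxn in mixed_network.reactions:
            for p in rxn.params:
                assert p in mixed_network.parameters


class TestApplyStrain:
    def test_deletion_zeroes_total(self, mixed_network):
        net = apply_strain(mixed_network, StrainSpec(deletions={"PBS2"}))
        v = net.conservation_vector("Pbs2")
        assert v @ net.initial_amounts() == 0.0
        # input unchanged
        assert mixed_network.conservation_vector("Pbs2") @ \
            mixed_network.initial_amounts() > 0

    def test_overexpression_scales_exactly(self, mixed_network):
        net = apply_strain(mixed_network,
                           StrainSpec(overexpression=(("Pbs2", 10.0),)))
        v = net.conservation_vector("Pbs2")
        assert v @ net.initial_amounts() == pytest.approx(
            10.0 * (mixed_network.conservation_vector("Pbs2")
                    @ mixed_network.initial_amounts()))

    def test_deletion_idempotent_and_commutes(self, mixed_network):
        s_del = StrainSpec(deletions={"SLN1"})
        once = apply_strain(mixed_network, s_del)
        twice = apply_strain(once, s_del)
        assert np.array_equal(once.initial_amounts(), twice.initial_amounts())
        s_over = StrainSpec(overexpression=(("Ptp2", 2.0),))
        ab = apply_strain(apply_strain(mixed_network, s_del), s_over)
        ba = apply_strain(apply_strain(mixed_network, s_over), s_del)
        assert np.array_equal(ab.initial_amounts(), ba.initial_amounts())

    def test_deleting_absent_protein_fails(self, mixed_network):
        with pytest.raises(StrainError):
            apply_strain(mixed_network, StrainSpec(deletions={"FUS3"}))

    def test_s248a_strips_affinity_from_feedback_binding(self, mixed_network):
        net = apply_strain(mixed_network, StrainSpec(pbs2_s248="S248A"))
        fb_bind = [r for r in net.reactions if r.name == "hog1_binding_fb"][0]
        assert "fb_affinity" not in fb_bind.params
        fb_first = [r for r in net.reactions if r.name == "hog1_first_phospho_fb"][0]
        assert "fb_catalytic" in fb_first.params  # catalytic component untouched

    def test_s248e_boosts_base_association(self, mixed_network):
        net = apply_strain(mixed_network, StrainSpec(pbs2_s248="S248E"))
        base_bind = [r for r in net.reactions if r.name == "hog1_binding"][0]
        assert "fb_affinity" in base_bind.params

    def test_ssk2_feedback_dead_removes_negative_feedback(self, mixed_network):
        net = apply_strain(mixed_network, StrainSpec(ssk2_feedback_dead=True))
        assert not any(r.name == "ssk2_negative_feedback" for r in net.reactions)


class TestBasicCascade:
    def test_distributive_has_free_mono_species(self):
        net = build_basic_cascade("distributive")
        assert "K_P" in net.species_names
        released = any("K_P" in {sp for sp, _ in r.products}
                       and r.name == "mapkp_dissociation"
                       for r in net.reactions)
        assert released

    def test_processive_has_no_mono_release(self):
        net = build_basic_cascade("processive")
        assert not any("dissociation" in r.name and "mapkp" in r.name
                       for r in net.reactions)

    @pytest.mark.parametrize("mechanism", ["distributive", "processive"])
    def test_conservation(self, mechanism):
        net = build_basic_cascade(mechanism)
        N = net.stoichiometry_matrix()
        for protein in ("MAPKKK", "MAPKK", "MAPK"):
            assert np.allclose(net.conservation_vector(protein) @ N, 0.0)

    def test_processive_dose_response_monotone(self):
        from hogpath.analysis import dose_response

        net = build_basic_cascade("processive")
        doses = np.geomspace(0.01, 3.0, 7)
        resp = dose_response(net, doses, rtol=1e-6, atol=1e-9)
        assert np.all(np.isfinite(resp))
        assert np.all(np.diff(resp) >= -1e-6)
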