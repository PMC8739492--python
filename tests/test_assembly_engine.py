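"""Forward co-linear assembly: chain state, position map, β-branching,
termination, tailoring and SMILES output."""

import pytest
from rdkit import Chem

import palcolin as pc
from palcolin import synthetic_data as sd
from palcolin.assembly_engine import (
    HCSCassette, apply_beta_branch, apply_elongation, apply_tailoring,
    compute_position_map, initialize_chain, terminate_and_cyclize,
)
from palcolin.bgc_model import DomainAnnotation, ModuleSpec, ROLE_ELONGATION, \
    ROLE_TERMINATION
from palcolin.errors import AssemblyError, TailoringError


def _module(index, kinds, kr_type=None, shift=False, trans=frozenset(),
            ordinal=1):
    doms = []
    for k in kinds:
        attrs = {}
        if k == "KR" and kr_type:
            attrs["kr_type"] = kr_type
        if k == "DH" and shift:
            attrs["shift"] = True
        doms.append(DomainAnnotation(kind=k, attrs=attrs))
    return ModuleSpec(index=index, role=ROLE_ELONGATION, domains=tuple(doms),
                      elongation_ordinal=ordinal, trans_annotations=trans)


def _term(catalytic=True):
    return ModuleSpec(index=99, role=ROLE_TERMINATION,
                      domains=(DomainAnnotation(
                          kind="C_trunc", attrs={"catalytic_his": catalytic}),))


class TestInitializeChain:
    def test_methylcrotonate_glycine_contributions(self):
        chain = initialize_chain("3-methylcrotonic acid", ["glycine"])
        assert chain.starter.carbon_count == 5
        from palcolin.bgc_model import AMINO_ACID_CONTRIBUTIONS
        glycine = AMINO_ACID_CONTRIBUTIONS["glycine"]
        assert glycine["backbone_carbons"] == 2
        assert glycine["heteroatoms"] == {"N": 1}
        assert chain.open and chain.units == []

    def test_butenoate_isomer_has_terminal_olefin(self):
        chain = initialize_chain("3-methyl-3-butenoic acid", [])
        assert chain.starter.terminal_olefin

    def test_unknown_monomer_rejected(self):
        with pytest.raises(AssemblyError, match="foo"):
            initialize_chain("foo", [])


class TestElongationRules:
    def test_kr_b_with_llm_gives_d_hydroxyl_and_alpha_hydroxyl(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(9, ["KS", "KR", "LLM", "ACP"], "B"))
        unit = chain.units[0]
        assert unit.beta_state == "hydroxyl_D"
        assert unit.alpha_hydroxyl

    def test_dh_without_kr_permissive_gives_shifted_olefin_with_methyl(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(3, ["KS", "DH", "cMT", "ACP"],
                                        shift=True))
        unit = chain.units[0]
        assert unit.beta_state == "olefin_shifted"
        assert unit.alpha_methyls == 1

    def test_dh_without_kr_strict_mode_warns_and_keeps_ketone(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(3, ["KS", "DH", "ACP"]),
                         permissive_dh=False)
        assert chain.units[0].beta_state == "ketone"
        assert any("DH without KR" in w for w in chain.warnings)

    def test_trans_er_reduces_the_olefin_to_saturation(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(8, ["KS", "DH", "KR", "ACP"], "B",
                                        trans=frozenset({"trans_ER"})))
        assert chain.units[0].beta_state == "saturated"

    @pytest.mark.parametrize("kr_type,geometry", [("A", "cis"), ("B", "trans")])
    def test_kr_dh_olefin_geometry(self, kr_type, geometry):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(7, ["KS", "DH", "KR", "ACP"], kr_type))
        assert chain.units[0].beta_state == "olefin"
        assert chain.units[0].geometry == geometry

    def test_closed_chain_rejects_elongation(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(1, ["KS", "ACP"]))
        terminate_and_cyclize(chain, _term())
        with pytest.raises(AssemblyError, match="closed"):
            apply_elongation(chain, _module(2, ["KS", "ACP"]))

    def test_non_elongation_module_rejected(self):
        chain = initialize_chain("acetate", [])
        with pytest.raises(AssemblyError, match="role"):
            apply_elongation(chain, _term())


class TestPositionMap:
    def test_printed_positions_for_eleven_elongations(self):
        pmap = compute_position_map(11)
        assert pmap.alpha(11) == 2          # final module's olefin at Δ2
        assert pmap.beta(3) == 19           # macrolactonization hydroxyl
        assert pmap.beta(9) == 7
        assert pmap.beta(4) == 17
        assert pmap.alpha(7) == 10
        assert pmap.alpha(5) == 14

    def test_identities_and_bijectivity(self):
        for E in (1, 3, 5, 11):
            pmap = compute_position_map(E)
            assert pmap.alpha(E) == 2
            assert pmap.beta(1) == 2 * E + 1
            carbons = [pmap.alpha(e) for e in range(1, E + 1)]
            carbons += [pmap.alpha(e) - 1 for e in range(1, E + 1)]
            assert sorted(carbons) == list(range(1, 2 * E + 1))

    def test_matches_chain_walk_oracle(self):
        # independent renumbering: walk the finished chain from the
        # thioester end; unit e contributes carbons in reverse assembly order
        E = 5
        pmap = compute_position_map(E)
        walk = {}
        carbon = 1
        for e in range(E, 0, -1):       # last-assembled unit is nearest C1
            walk[e] = {"carbonyl": carbon, "alpha": carbon + 1}
            carbon += 2
        for e in range(1, E + 1):
            assert pmap.alpha(e) == walk[e]["alpha"]
            assert pmap.beta(e) == walk[e]["alpha"] + 1

    def test_invalid_elongation_counts(self):
        with pytest.raises(AssemblyError):
            compute_position_map(0)
        with pytest.raises(AssemblyError):
            compute_position_map(3).alpha(4)


class TestBetaBranch:
    def _site(self, state="ketone", hcs=True):
        from palcolin.assembly_engine import BackboneUnit
        return BackboneUnit(elongation_ordinal=4, origin_module=6,
                            beta_state=state, hcs_site=hcs)

    def test_full_cassette_installs_internal_branch(self):
        chain = initialize_chain("acetate", [])
        site = self._site()
        chain.units.append(site)
        apply_beta_branch(chain, HCSCassette(), site)
        assert site.beta_branch == {"mode": "internal"}

    def test_non_ketone_site_is_a_substrate_error(self):
        chain = initialize_chain("acetate", [])
        site = self._site(state="hydroxyl_D")
        with pytest.raises(AssemblyError, match="ketone"):
            apply_beta_branch(chain, HCSCassette(), site)

    def test_incomplete_cassette_rejected(self):
        chain = initialize_chain("acetate", [])
        with pytest.raises(AssemblyError, match="incomplete"):
            apply_beta_branch(chain, HCSCassette(hcs=False), self._site())


class TestTermination:
    def test_pal_bgc_4_macrolactonizes_at_c19(self, bgc4_structure):
        assert bgc4_structure.ring_closure == (1, 19)

    def test_all_ketone_chain_released_linear_with_warning(self):
        chain = initialize_chain("acetate", [])
        for i in range(3):
            apply_elongation(chain, _module(i + 1, ["KS", "ACP"],
                                            ordinal=i + 1))
        s = terminate_and_cyclize(chain, _term())
        assert s.ring_closure is None
        assert any("linear" in w for w in s.warnings)

    def test_termination_without_catalytic_histidine_fails(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(1, ["KS", "ACP"]))
        with pytest.raises(AssemblyError, match="histidine"):
            terminate_and_cyclize(chain, _term(catalytic=False))


class TestTailoring:
    def test_carbamate_at_c11(self, bgc4_structure):
        assert bgc4_structure.decorations[11] == ("carbamate",)

    def test_palmerolide_b_decoration_pattern(self, bgc4):
        s = pc.assemble(bgc4, ct_target=7,
                        extra_tailoring=(
                            {"enzyme": "sulfotransferase", "target": 11},))
        assert s.decorations == {7: ("carbamate",), 11: ("sulfate",)}

    def test_target_without_hydroxyl_is_a_tailoring_error(self, bgc4):
        with pytest.raises(TailoringError):
            pc.assemble(bgc4, ct_target=3)

    def test_targets_are_consumed_no_double_decoration(self, bgc4):
        s = pc.assemble(bgc4)
        with pytest.raises(TailoringError, match="already applied"):
            apply_tailoring(s, [{"enzyme": "CT", "target": 11}])
            apply_tailoring(s, [{"enzyme": "CT", "target": 11}])


class TestAssemble:
    def test_pal_bgc_4_full_feature_set(self, bgc4_structure):
        s = bgc4_structure
        assert s.n_elongations == 11
        assert s.polyketide_carbon_count == 22
        assert s.backbone_carbon_count == 24
        assert s.olefins[2] == "trans"
        assert s.olefins[8] == "trans"
        assert s.olefins[14] == "trans"
        assert 21 in s.olefins and 23 in s.olefins   # shifted β,γ olefins
        assert s.hydroxyls[7] == "D"
        assert s.hydroxyls[10] is None               # α-hydroxyl
        assert s.branch_sites == {17: "internal"}
        assert 16 in s.olefins                       # conjugated with the branch
        assert s.ring_closure == (1, 19)
        assert s.amide

    def test_elongation_only_cluster_gives_10_polyketide_carbons(self, pal_archs):
        s = pc.assemble(pal_archs["pal_bgc_2"])
        assert s.n_elongations == 5
        assert s.polyketide_carbon_count == 10
        assert s.ring_closure is None

    @pytest.mark.parametrize("seed", range(60))
    def test_carbon_conservation_on_synthetic_runs(self, seed):
        arch, _ = sd.simulate_architecture(sd.SimulationConfig(seed=seed))
        s = pc.assemble(arch)
        n_alpha_methyls = sum(
            len(f.branch_methyls) for f in s.features.values()
            if f.branch_mode is None)
        n_branch_methyls = sum(
            len(f.branch_methyls) for f in s.features.values()
            if f.branch_mode is not None)
        starter_c = s.starter.carbon_count if s.starter else 0
        aa_c = 2 * len(s.amino_acids)
        primer_c = 2 if (s.starter is None and not s.amino_acids) else 0
        assert s.total_carbon_count == (
            starter_c + 2 * s.n_elongations + aa_c
            + n_alpha_methyls + n_branch_methyls + primer_c)

    @pytest.mark.parametrize("seed", range(40))
    def test_olefin_geometry_follows_kr_type(self, seed):
        arch, _ = sd.simulate_architecture(sd.SimulationConfig(seed=seed))
        s = pc.assemble(arch)
        pmap = compute_position_map(max(s.n_post_nrps, 1))
        for m in arch.elongation_modules:
            kr = next((d for d in m.domains if d.kind == "KR"), None)
            has_dh = any(d.kind == "DH" for d in m.domains)
            shifted = any(d.attrs.get("shift") for d in m.domains)
            if kr is None or not has_dh or shifted:
                continue
            if "trans_ER" in m.trans_annotations:
                continue
            e = m.elongation_ordinal
            if kr.kr_type == "A":
                assert s.olefins.get(pmap.alpha(e)) == "cis"
            elif kr.kr_type == "B":
                assert s.olefins.get(pmap.alpha(e)) == "trans"


class TestSmiles:
    def test_linear_diketide_has_four_carbons(self):
        chain = initialize_chain("acetate", [])
        apply_elongation(chain, _module(1, ["KS", "ACP"]))
        s = terminate_and_cyclize(chain, _term())
        mol = Chem.MolFromSmiles(pc.to_smiles(s))
        assert sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C") == 4

    @pytest.mark.parametrize("seed", range(30))
    def test_formula_matches_feature_table_totals(self, seed):
        arch, _ = sd.simulate_architecture(sd.SimulationConfig(seed=seed))
        s = pc.assemble(arch)
        mol = Chem.MolFromSmiles(pc.to_smiles(s))
        assert mol is not None
        n_c = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
        n_n = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N")
        n_carbamate = sum(f.decorations.count("carbamate")
                          for f in s.features.values())
        assert n_c == s.total_carbon_count + n_carbamate
        expected_n = len(s.amino_acids) + n_carbamate
        assert n_n == expected_n

    def test_palmerolide_a_smiles_has_ring_ester_and_carbamate(self, bgc4_structure):
        mol = Chem.MolFromSmiles(pc.to_smiles(bgc4_structure))
        carbamate = Chem.MolFromSmarts("OC(=O)N")
        ring_ester = Chem.MolFromSmarts("[C;R](=O)[O;R]")
        assert mol.HasSubstructMatch(carbamate)
        assert mol.HasSubstructMatch(ring_ester)
        assert mol.GetRingInfo().NumRings() == 1
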