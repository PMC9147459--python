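"""Built-in filter definitions, the rule engine, and the pharmacophore filter."""

import dataclasses

import pytest

from medchemfilters.chem_io import parse_smiles
from medchemfilters.descriptors import compute_descriptors
from medchemfilters.property_filters import (
    FilterDefinition,
    FilterRule,
    amine_pharmacophore_points,
    builtin_filter,
    builtin_filter_names,
    evaluate,
    filter_from_dict,
    filter_to_dict,
    load_filter,
    muegge_evaluate,
    save_filter,
)


def make_dv(**overrides):
    """A benign descriptor vector; override only what a rule reads."""
    base = dict(
        slogp=2.0, smr=80.0, tpsa=60.0, mw=350.0, rot_bonds=4, hba=4, hbd=2,
        heavy_atoms=25, rings=2, aromatic_rings=1, total_atoms_incl_h=40,
        formal_charge=0, halogens=0, n_count=2, o_count=2, c_count=20,
        carboxylic_acids=0, nonterminal_single_bonds=5, branch_points=4,
        logd=None,
    )
    base.update(overrides)
    from medchemfilters.descriptors import DescriptorVector
    return DescriptorVector(**base)


class TestBuiltinDefinitions:
    def test_lipinski_four_rules_one_break(self):
        f = builtin_filter("lipinski")
        assert len(f.rules) == 4
        assert f.allowed_breaks == 1
        bounds = {r.descriptor: r.upper for r in f.rules}
        assert bounds == {"mw": 500, "slogp": 5, "hbd": 5, "hba": 10}

    def test_ro4_lower_bounds(self):
        f = builtin_filter("ro4")
        bounds = {r.descriptor: r.lower for r in f.rules}
        assert bounds == {"mw": 400, "slogp": 4, "rings": 4, "hba": 4}

    def test_mozziconacci_five_rules(self):
        f = builtin_filter("mozziconacci")
        assert len(f.rules) == 5
        by_name = {r.descriptor: r for r in f.rules}
        assert by_name["o_count"].lower == 1
        assert by_name["n_count"].lower == 1
        assert by_name["halogens"].upper == 7

    def test_unknown_name_lists_available(self):
        with pytest.raises(KeyError, match="lipinski"):
            builtin_filter("nope")

    def test_all_names_resolve(self):
        for name in builtin_filter_names():
            assert builtin_filter(name).rules


class TestEvaluate:
    def test_lipinski_tolerates_one_break(self):
        v = evaluate(builtin_filter("lipinski"), make_dv(mw=550, slogp=4, hbd=2, hba=8))
        assert v.passed and len(v.violations) == 1
        assert "mw" in v.violations[0]

    def test_lipinski_fails_on_two_breaks(self):
        v = evaluate(builtin_filter("lipinski"), make_dv(mw=550, slogp=6, hbd=2, hba=8))
        assert not v.passed and len(v.violations) == 2

    def test_mid_range_vector_passes_everything_applicable(self):
        d = make_dv()
        for name in builtin_filter_names():
            f = builtin_filter(name)
            if any(r.descriptor == "logd" for r in f.rules) and name != "oprea":
                continue
            if name in {"ro3", "ro4"}:
                continue  # regime-specific filters; the mid-range vector
                # sits outside both by design
            v = evaluate(f, d)
            assert v.passed, (name, v.violations)

    def test_veber_bounds_inclusive(self):
        v = evaluate(builtin_filter("veber"), make_dv(rot_bonds=10, tpsa=140.0))
        assert v.passed and not v.violations

    def test_murcko_aromatic_ring_bound_strict(self):
        f = builtin_filter("murcko")
        ok = make_dv(mw=300, slogp=2, hba=3, hbd=1, rot_bonds=2,
                     branch_points=5, aromatic_rings=2)
        assert evaluate(f, ok).passed
        at_bound = dataclasses.replace(ok, aromatic_rings=3)
        v = evaluate(f, at_bound)
        assert not v.passed and any("aromatic_rings" in x for x in v.violations)

    def test_oprea_mw_bound_strict_as_printed(self):
        f = builtin_filter("oprea")
        assert not evaluate(f, make_dv(mw=450.0)).passed
        assert evaluate(f, make_dv(mw=449.9)).passed

    def test_fichert_without_logd_is_unevaluable(self):
        v = evaluate(builtin_filter("fichert"), make_dv(logd=None))
        assert not v.passed and v.unevaluable

    def test_fichert_with_supplied_logd(self):
        assert evaluate(builtin_filter("fichert"), make_dv(logd=1.5)).passed
        assert not evaluate(builtin_filter("fichert"), make_dv(logd=3.5)).passed

    def test_fichert_slogp_substitution_opt_in(self):
        v = evaluate(
            builtin_filter("fichert"), make_dv(logd=None, slogp=2.0),
            substitute_slogp_for_logd=True,
        )
        assert v.passed and not v.unevaluable

    def test_oprea_logd_window_optional_when_absent(self):
        assert evaluate(builtin_filter("oprea"), make_dv(logd=None)).passed
        assert not evaluate(builtin_filter("oprea"), make_dv(logd=5.0)).passed

    def test_determinism(self):
        d = make_dv(mw=501)
        f = builtin_filter("lipinski")
        assert evaluate(f, d) == evaluate(f, d)


class TestMuegge:
    def test_two_carboxylic_acids_dismissed(self):
        m = parse_smiles("OC(=O)CCC(=O)O")
        v = muegge_evaluate(m, compute_descriptors(m))
        assert not v.passed and "carboxylic_acids>1" in v.violations

    def test_no_ring_dismissed(self):
        m = parse_smiles("CCCCCC")
        v = muegge_evaluate(m, compute_descriptors(m))
        assert not v.passed and "no_ring" in v.violations

    def test_aniline_passes_with_one_amine_point(self):
        m = parse_smiles("Nc1ccccc1")
        v = muegge_evaluate(m, compute_descriptors(m))
        assert v.passed
        assert v.details["amine_pharmacophore_points"] == 1

    def test_piperazine_intracyclic_amines_fuse(self):
        assert amine_pharmacophore_points(parse_smiles("C1CNCCN1")) == 1

    @pytest.mark.parametrize(
        "smiles",
        ["c1cc[nH]c1", "c1ccc2[nH]ccc2c1", "c1cscn1", "c1ccon1", "c1ccncn1"],
        ids=["pyrrole", "indole", "thiazole", "isoxazole", "pyrimidine"],
    )
    def test_excluded_heterocycles_contribute_no_points(self, smiles):
        assert amine_pharmacophore_points(parse_smiles(smiles)) == 0

    def test_amide_nitrogen_not_an_amine(self):
        assert amine_pharmacophore_points(parse_smiles("CC(=O)NC")) == 0

    def test_optional_point_window(self):
        m = parse_smiles("c1ccccc1")  # ring, no amines
        d = compute_descriptors(m)
        assert muegge_evaluate(m, d).passed
        assert not muegge_evaluate(m, d, min_points=1).passed


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        f = builtin_filter("oprea")
        p = tmp_path / "oprea.yaml"
        save_filter(f, p)
        assert load_filter(p) == f

    def test_dict_round_trip_preserves_strictness(self):
        f = builtin_filter("murcko")
        assert filter_from_dict(filter_to_dict(f)) == f

    def test_custom_filter_definition(self):
        f = FilterDefinition(
            name="tiny", rules=(FilterRule("mw", upper=250),), allowed_breaks=0
        )
        assert evaluate(f, make_dv(mw=200)).passed
        assert not evaluate(f, make_dv(mw=300)).passed

    def test_invalid_definitions_rejected(self):
        with pytest.raises(ValueError):
            FilterRule("mw")
        with pytest.raises(ValueError):
            FilterRule("mw", lower=10, upper=5)
        with pytest.raises(ValueError):
            FilterDefinition("bad", (FilterRule("mw", upper=1),), allowed_breaks=1)
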