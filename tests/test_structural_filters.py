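"""PAINS/REOS catalog screens: probe firing, tuning, round trips."""

import pytest
from rdkit.Chem import FilterCatalog as RDFilterCatalog

from medchemfilters.chem_io import parse_smiles
from medchemfilters.descriptors import compute_descriptors
from medchemfilters.fixtures import functional_group_probes
from medchemfilters.structural_filters import (
    Catalog,
    SmartsPattern,
    load_catalog,
    reos_full,
    save_catalog,
    screen,
)

PROBES = functional_group_probes()


def probes_for(catalog_name):
    return [p for p in PROBES if p.expected.get(catalog_name, "absent") is not None
            and catalog_name in p.expected]


def controls_for(catalog_name):
    return [p for p in PROBES if catalog_name in p.expected
            and p.expected[catalog_name] is None]


class TestCatalogLoading:
    def test_pains_families_include_catechols_and_quinones(self, pains_catalog):
        names = {p.name for p in pains_catalog.patterns}
        assert "catechol" in names
        assert any(n.startswith("quinone") for n in names)

    def test_reos_includes_nitro(self, reos_catalog):
        assert "nitro" in {p.name for p in reos_catalog.patterns}

    def test_custom_single_line_file(self, tmp_path):
        p = tmp_path / "custom.smarts"
        p.write_text("aldehyde [CX3H1]=O 0\n")
        cat = load_catalog(p)
        assert len(cat.patterns) == 1
        assert cat.patterns[0].max_count == 0

    def test_invalid_smarts_aborts_with_line(self, tmp_path):
        p = tmp_path / "bad.smarts"
        p.write_text("ok [CX3H1]=O\nbroken [[[\n")
        with pytest.raises(ValueError, match=":2"):
            load_catalog(p)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Catalog("c", (SmartsPattern("x", "[#6]"), SmartsPattern("x", "[#8]")))

    def test_unknown_source_is_fatal(self):
        with pytest.raises(FileNotFoundError):
            load_catalog("no_such_catalog")

    def test_file_round_trip(self, tmp_path, reos_catalog):
        p = tmp_path / "reos_copy.smarts"
        save_catalog(reos_catalog, p)
        back = load_catalog(p)
        assert back.patterns == reos_catalog.patterns


class TestScreen:
    @pytest.mark.parametrize("probe", probes_for("reos"), ids=lambda p: p.note)
    def test_reos_probe_fires_exactly_its_pattern(self, probe, reos_catalog):
        v = screen(parse_smiles(probe.smiles), reos_catalog)
        assert not v.passed
        assert v.matches == [probe.expected["reos"]]

    @pytest.mark.parametrize("probe", probes_for("pains"), ids=lambda p: p.note)
    def test_pains_probe_fires_exactly_its_pattern(self, probe, pains_catalog):
        v = screen(parse_smiles(probe.smiles), pains_catalog)
        assert not v.passed
        assert v.matches == [probe.expected["pains"]]

    @pytest.mark.parametrize("catalog_name", ["pains", "reos"])
    def test_inert_controls_pass(self, catalog_name, pains_catalog, reos_catalog):
        cat = pains_catalog if catalog_name == "pains" else reos_catalog
        for probe in controls_for(catalog_name):
            v = screen(parse_smiles(probe.smiles), cat)
            assert v.passed and not v.matches, probe.note

    def test_quinone_fails_pains(self, pains_catalog):
        v = screen(parse_smiles("O=C1C=CC(=O)C=C1"), pains_catalog)
        assert not v.passed and "quinone_para" in v.matches

    def test_raising_max_count_admits_nitrobenzene(self, reos_catalog):
        m = parse_smiles("O=[N+]([O-])c1ccccc1")
        assert not screen(m, reos_catalog).passed
        tuned = reos_catalog.with_max_count("nitro", 1)
        assert screen(m, tuned).passed

    def test_max_count_monotonicity_on_probe_set(self, reos_catalog):
        """Raising any pattern's max_count never shrinks the pass set."""
        mols = [parse_smiles(p.smiles) for p in PROBES]
        base_pass = {m.canonical_smiles for m in mols if screen(m, reos_catalog).passed}
        for pattern in reos_catalog.patterns:
            tuned = reos_catalog.with_max_count(pattern.name, pattern.max_count + 2)
            tuned_pass = {
                m.canonical_smiles for m in mols if screen(m, tuned).passed
            }
            assert base_pass <= tuned_pass

    def test_screen_independent_of_other_records(self, reos_catalog):
        a = parse_smiles("O=Cc1ccccc1")
        alone = screen(a, reos_catalog)
        for other in ["CCO", "O=[N+]([O-])c1ccccc1"]:
            screen(parse_smiles(other), reos_catalog)
            assert screen(a, reos_catalog) == alone


class TestAgainstRDKitPainsCatalog:
    """Independent cross-check: the full published PAINS set as compiled in
    RDKit's FilterCatalog also flags our PAINS probes."""

    @pytest.fixture()
    def rdkit_pains(self):
        params = RDFilterCatalog.FilterCatalogParams()
        params.AddCatalog(RDFilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        return RDFilterCatalog.FilterCatalog(params)

    @pytest.mark.parametrize(
        "smiles", ["Oc1ccccc1O", "O=C1C=CC(=O)C=C1", "O=C1CSC(=S)N1"],
        ids=["catechol", "quinone", "rhodanine"],
    )
    def test_canonical_families_flagged_by_both(self, smiles, rdkit_pains, pains_catalog):
        m = parse_smiles(smiles)
        assert rdkit_pains.HasMatch(m.structure)
        assert not screen(m, pains_catalog).passed

    def test_inert_controls_clean_in_both(self, rdkit_pains, pains_catalog):
        for probe in controls_for("pains"):
            m = parse_smiles(probe.smiles)
            assert not rdkit_pains.HasMatch(m.structure)
            assert screen(m, pains_catalog).passed


class TestReosHybrid:
    def test_charge_outside_window_fails_hybrid_only(self, reos_catalog):
        m = parse_smiles("OC(CC([O-])=O)(CC([O-])=O)C([O-])=O")  # citrate trianion
        d = compute_descriptors(m)
        assert d.formal_charge == -3
        assert not reos_full(m, d, mode="hybrid").passed
        assert reos_full(m, d, mode="structural_only").passed

    def test_ethane_fails_heavy_atom_floor_only_in_hybrid(self):
        m = parse_smiles("CC")
        d = compute_descriptors(m)
        hybrid = reos_full(m, d, mode="hybrid")
        assert not hybrid.passed
        assert any("heavy_atoms" in v for v in hybrid.violations)
        assert reos_full(m, d, mode="structural_only").passed

    def test_drug_like_neutral_fixture_passes_both_modes(self):
        # a ~22-heavy-atom neutral amide with no flagged groups; each of the
        # seven property bounds is re-verified directly before the screen
        m = parse_smiles("COc1ccc2cc(ccc2c1)C(C)C(=O)N1CCCCC1")  # naproxen piperidide
        d = compute_descriptors(m)
        assert d.hbd <= 5 and d.hba <= 10 and -2 <= d.formal_charge <= 2
        assert d.rot_bonds <= 8 and 200 <= d.mw <= 500
        assert 20 <= d.heavy_atoms <= 50 and -2 <= d.slogp <= 5
        assert reos_full(m, d, mode="hybrid").passed
        assert reos_full(m, d, mode="structural_only").passed

    def test_invalid_mode_rejected(self):
        m = parse_smiles("CC")
        with pytest.raises(ValueError):
            reos_full(m, compute_descriptors(m), mode="bogus")
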