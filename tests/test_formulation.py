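import math

import pytest
from hypothesis import given, settings, strategies as st

from exomedium.chem import ElementTally, parse_formula
from exomedium.formulation import (
    MediumComponent,
    MediumDefinition,
    MediumFormatError,
    SaltProfile,
    cn_ratio,
    element_mass_concentration,
    read_medium,
    recipe,
    solve_cn_scale,
    solve_tier_scale,
    stoichiometry_table,
    total_element_mass,
    write_medium,
)

from conftest import AMINO_ACID_FORMULAS

GLUCOSE = MediumComponent("glucose", parse_formula("C6H12O6"), "sugars", 875.0)
GLYCINE = MediumComponent("glycine", parse_formula("C2H5NO2"), "amino_acids", 175.0)


def amino_acid_medium():
    return MediumDefinition(
        name="amino acids only",
        components=tuple(
            MediumComponent(n, parse_formula(f), "amino_acids", 175.0)
            for n, f in AMINO_ACID_FORMULAS.items()
        ),
    )


class TestElementMass:
    def test_glucose_carbon(self):
        assert element_mass_concentration(GLUCOSE, "C") == pytest.approx(63.06, abs=0.005)

    def test_glycine_nitrogen(self):
        assert element_mass_concentration(GLYCINE, "N") == pytest.approx(2.45, abs=0.005)

    def test_absent_element_is_zero(self):
        assert element_mass_concentration(GLUCOSE, "N") == 0.0


class TestStoichiometryTable:
    def test_amino_acid_tier_matches_printed_budget(self):
        """The 20 standard amino acids at 175 µM give 225 mg/L C, 71 mg/L N."""
        table = stoichiometry_table(amino_acid_medium(), rounded=True)
        row = table.loc["amino_acids"]
        assert (row["uM_each"], row["n_compounds"]) == (175.0, 20)
        assert (row["C_mg_L"], row["N_mg_L"]) == (225, 71)

    def test_single_glucose_row(self):
        m = MediumDefinition(name="g", components=(GLUCOSE,))
        row = stoichiometry_table(m).loc["sugars"]
        assert row["n_compounds"] == 1
        assert row["C_mg_L"] == pytest.approx(63.058, abs=1e-3)
        assert row["N_mg_L"] == 0.0

    def test_empty_medium_all_zero(self):
        table = stoichiometry_table(MediumDefinition(name="empty", components=()))
        assert (table[["C_mg_L", "N_mg_L"]] == 0).all().all()
        assert (table["n_compounds"] == 0).all()

    def test_totals_row_equals_component_sums(self, nldm):
        table = stoichiometry_table(nldm)
        assert table.loc["total", "C_mg_L"] == pytest.approx(
            total_element_mass(nldm, "C"), rel=1e-12
        )
        group_sum = table.drop(index="total")["C_mg_L"].sum()
        assert table.loc["total", "C_mg_L"] == pytest.approx(group_sum, rel=1e-9)

    def test_totals_row_rounds_from_full_precision(self, nldm):
        # the rounded totals row comes from the unrounded total, so it may
        # legitimately differ from the sum of the rounded group rows
        rounded = stoichiometry_table(nldm, rounded=True)
        assert rounded.loc["total", "C_mg_L"] == 1042
        assert rounded.drop(index="total")["C_mg_L"].sum() == 1041


class TestCNRatio:
    def test_equal_molar_c_and_n_gives_one(self):
        m = MediumDefinition(
            name="cn", components=(MediumComponent("x", ElementTally({"C": 1, "N": 1}), "other", 100.0),)
        )
        assert cn_ratio(m, basis="molar") == pytest.approx(1.0)

    def test_printed_ratio_reproduced_with_ammonium(self, nldm):
        # molar basis including the 1 mM ammonium N is the reading that
        # rounds to the published 9:1
        assert cn_ratio(nldm, basis="molar", include_inorganic_n=True) == pytest.approx(
            8.86, abs=0.01
        )
        assert round(cn_ratio(nldm, basis="molar", include_inorganic_n=True)) == 9

    def test_no_nitrogen_raises(self):
        m = MediumDefinition(name="g", components=(GLUCOSE,))
        with pytest.raises(ZeroDivisionError):
            cn_ratio(m, include_inorganic_n=False)

    def test_scaling_leaves_organic_ratio_unchanged(self, nldm):
        assert cn_ratio(nldm.scaled(2.0)) == pytest.approx(cn_ratio(nldm), rel=1e-12)
        assert total_element_mass(nldm.scaled(2.0), "C") == pytest.approx(
            2 * total_element_mass(nldm, "C"), rel=1e-12
        )


class TestSolver:
    def test_glucose_inverse_example(self):
        base = solve_tier_scale([(parse_formula("C6H12O6"), 1.0)], 63.05775)
        assert base == pytest.approx(875.0, rel=1e-9)

    def test_no_carbon_raises(self):
        with pytest.raises(ValueError, match="carbon"):
            solve_tier_scale([(parse_formula("H2O"), 1.0)], 10.0)

    def test_cn_scale_reaches_target(self, nldm):
        s = solve_cn_scale(nldm, 8.0, basis="molar")
        scaled = nldm.scaled(s)
        assert cn_ratio(scaled, basis="molar", include_inorganic_n=True) == pytest.approx(
            8.0, rel=1e-9
        )

    def test_cn_scale_infeasible_above_organic_ratio(self, nldm):
        with pytest.raises(ValueError, match="not reachable"):
            solve_cn_scale(nldm, 100.0, basis="molar")


_formulas = st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S"]), st.integers(1, 30), min_size=1, max_size=5
).map(ElementTally)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    comps=st.lists(
        st.tuples(_formulas, st.floats(0.01, 100.0, allow_nan=False)), min_size=1, max_size=8
    ),
    target=st.floats(0.1, 5000.0, allow_nan=False),
)
def test_tier_solver_inverse_consistency(comps, target):
    """Forward C computation at the solved base recovers the target exactly."""
    if not any(t.count("C") for t, _ in comps):
        comps = comps + [(ElementTally({"C": 6, "H": 12, "O": 6}), 1.0)]
    base = solve_tier_scale(comps, target)
    total_c = sum(m * t.count("C") * 12.011 * 1e-3 * base for t, m in comps)
    assert total_c == pytest.approx(target, rel=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    comps=st.lists(
        st.tuples(_formulas, st.floats(0.1, 1000.0, allow_nan=False)), min_size=1, max_size=6,
    ),
    factor=st.floats(0.1, 10.0, allow_nan=False),
)
def test_scaling_doubles_masses_not_ratio(comps, factor):
    components = tuple(
        MediumComponent(f"c{i}", t, "other", conc) for i, (t, conc) in enumerate(comps)
    )
    m = MediumDefinition(name="m", components=components)
    scaled = m.scaled(factor)
    for el in ("C", "N"):
        assert total_element_mass(scaled, el) == pytest.approx(
            factor * total_element_mass(m, el), rel=1e-9
        )
    if total_element_mass(m, "N") > 0:
        assert cn_ratio(scaled) == pytest.approx(cn_ratio(m), rel=1e-9)


class TestRecipe:
    def test_glucose_mass(self):
        m = MediumDefinition(name="g", components=(GLUCOSE,))
        r = recipe(m)
        assert r.loc[r["name"] == "glucose", "mg_L"].iloc[0] == pytest.approx(157.64, abs=0.01)

    def test_nldm_recipe_has_64_metabolite_lines(self, nldm):
        r = recipe(nldm)
        assert (r["kind"] == "metabolite").sum() == 64
        assert (r["kind"] == "salt").sum() == len(nldm.salts.mM)

    def test_zero_concentration_rejected_upstream(self):
        with pytest.raises(ValueError):
            MediumComponent("x", parse_formula("C"), "other", 0.0)


class TestMediumIO:
    def test_roundtrip_json_and_tsv(self, nldm, tmp_path):
        for dialect in ("json", "tsv"):
            path = tmp_path / f"m.{dialect}"
            write_medium(nldm, path, dialect=dialect)
            back = read_medium(path, dialect=dialect)
            assert back == nldm

    def test_tsv_and_json_give_equal_definitions(self, nldm, tmp_path):
        write_medium(nldm, tmp_path / "m.json")
        write_medium(nldm, tmp_path / "m.tsv")
        assert read_medium(tmp_path / "m.json") == read_medium(tmp_path / "m.tsv")

    def test_unknown_group_names_the_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "kind\tname\tformula\tgroup\tconc_uM\tmM\tfold\tsource\tinorganic_n\tph_low\tph_high\n"
            "component\tglucose\tC6H12O6\tsugars\t875\t\t\t\t\t\t\n"
            "component\tcholesterol\tC27H46O\tlipid\t10\t\t\t\t\t\t\n"
        )
        with pytest.raises(MediumFormatError, match="row 3.*lipid"):
            read_medium(path)

    def test_duplicate_component_names_rejected(self, tmp_path):
        import json

        d = {
            "name": "x", "ph": [7, 7.2],
            "components": [
                {"name": "glucose", "formula": "C6H12O6", "group": "sugars", "conc_uM": 1},
                {"name": "glucose", "formula": "C6H12O6", "group": "sugars", "conc_uM": 2},
            ],
        }
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(d))
        with pytest.raises(MediumFormatError, match="duplicate"):
            read_medium(path)

    def test_salt_profile_negative_rejected(self):
        with pytest.raises(ValueError):
            SaltProfile(mM={"ammonium": -1.0})
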