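"""Stratified combination matrix, replacement-transition matrix and the
per-genotype / per-category OR tables."""

import math

import numpy as np
import pandas as pd
import pytest

from cehrisk.association import ContingencyTable, odds_ratio
from cehrisk.catalog import MHCGroup, make_genotype
from cehrisk.errors import DegenerateTableError
from cehrisk.io import annotate_cohort
from cehrisk.matrices import (
    combination_matrix,
    mhc_genotype_ors,
    risk_combination_ors,
    transition_matrix,
    z_band,
)
from cehrisk.presets import study_like_config
from cehrisk.simulate import simulate_cohort

from conftest import make_cohort

G = MHCGroup


class TestMhcGenotypeOrs:
    def test_reference_row_is_exactly_one(self, study_cohort, catalog):
        table = mhc_genotype_ors(study_cohort, catalog).set_index("mhc_genotype")
        assert table.loc["(0,0)", "or"] == 1.0
        assert table.loc["(0,0)", "ln_or"] == 0.0

    def test_counts_match_row_scan_oracle(self, study_cohort, catalog):
        ann = annotate_cohort(study_cohort, catalog)
        table = mhc_genotype_ors(study_cohort, catalog).set_index("mhc_genotype")
        expected = ann[ann["mhc_genotype"] == "(0,H+)"]
        reference = ann[ann["mhc_genotype"] == "(0,0)"]
        a = int((expected["status"] == "case").sum())
        b = int((expected["status"] == "control").sum())
        c = int((reference["status"] == "case").sum())
        d = int((reference["status"] == "control").sum())
        direct = odds_ratio(ContingencyTable(a, b, c, d))
        assert table.loc["(0,H+)", "or"] == pytest.approx(direct.or_value, rel=1e-12)
        assert table.loc["(0,H+)", "n_exposed"] == a + b

    def test_rereference_equals_direct_computation(self, study_cohort, catalog):
        """Chain rule: OR(g vs (AP,AP)) = OR(g vs (0,0)) * OR((0,0) vs (AP,AP))."""
        via_00 = mhc_genotype_ors(study_cohort, catalog).set_index("mhc_genotype")
        via_ap = mhc_genotype_ors(
            study_cohort, catalog, reference=make_genotype(G.AP, G.AP)
        ).set_index("mhc_genotype")
        bridge = via_ap.loc["(0,0)", "or"]
        for g in ("(0,H+)", "(H+,H+)", "(0,c1)"):
            assert via_00.loc[g, "or"] * bridge == pytest.approx(via_ap.loc[g, "or"], rel=1e-10)

    def test_absent_reference_is_degenerate(self, catalog):
        coh = make_cohort([("case", "F", "H+", "H+", 0, 0, 0),
                           ("control", "M", "H+", "H+", 0, 0, 0)])
        with pytest.raises(DegenerateTableError):
            mhc_genotype_ors(coh, catalog)

    def test_bh_column_present_and_bounded(self, study_cohort, catalog):
        table = mhc_genotype_ors(study_cohort, catalog)
        adj = table["p_bh"].dropna()
        raw = table.loc[adj.index, "p_value"]
        assert (adj >= raw - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()


class TestRiskCombinationOrs:
    def test_sex_stratified_and_pooled(self, catalog):
        coh = simulate_cohort(
            study_like_config(seed=31, sex_effect=True, n_cases=4000, n_controls=6000)
        )
        res = risk_combination_ors(coh, catalog, by_sex=True)
        t = res.table.set_index(["risk_category", "sex"])
        assert ("single-copy-risk", "F") in t.index
        # configured female excess for the single-copy category only
        assert res.sex_comparison_single_copy_risk is not None
        f_or = t.loc[("single-copy-risk", "F"), "or"]
        m_or = t.loc[("single-copy-risk", "M"), "or"]
        assert np.sign(res.sex_comparison_single_copy_risk.ln_ratio) == np.sign(
            math.log(f_or / m_or)
        )

    def test_pooled_interface_without_sex(self, study_cohort, catalog):
        res = risk_combination_ors(study_cohort, catalog, by_sex=False)
        assert set(res.table["sex"]) == {"all"}
        assert res.sex_comparison_single_copy_risk is None

    def test_double_copy_protective_below_one(self, study_cohort, catalog):
        t = risk_combination_ors(study_cohort, catalog).table.set_index("risk_category")
        assert t.loc["double-copy-protective", "or"] < 1.0
        assert t.loc["double-copy-risk", "or"] > t.loc["single-copy-risk", "or"]


class TestCombinationMatrix:
    def test_cells_isolate_their_stratum(self, catalog, study_cohort):
        mat1 = combination_matrix(study_cohort, catalog)
        # append individuals in a different MHC stratum: (ER,ER) homozygotes
        extra = make_cohort(
            [("case", "F", "ER", "ER", 1, 1, 1)] * 30 + [("control", "M", "ER", "ER", 0, 0, 0)] * 30
        )
        extra["sample_id"] = "x" + extra["sample_id"]
        bigger = pd.concat([study_cohort, extra], ignore_index=True)
        mat2 = combination_matrix(bigger, catalog)
        col = "(0,H+)"
        c1 = mat1.cells[mat1.cells["column_genotype"] == col].set_index("row_combination")
        c2 = mat2.cells[mat2.cells["column_genotype"] == col].set_index("row_combination")
        pd.testing.assert_series_equal(c1["ln_or"], c2["ln_or"])

    def test_sparse_cell_flagged_na(self, catalog):
        records = (
            [("case", "F", "0", "0", 0, 0, 0)] * 50
            + [("control", "M", "0", "0", 0, 0, 0)] * 50
            + [("case", "F", "0", "0", 2, 0, 0)] * 7
            + [("control", "M", "0", "0", 2, 0, 0)] * 7
        )
        mat = combination_matrix(make_cohort(records), catalog)
        cell = mat.cells[
            (mat.cells["column_genotype"] == "(0,0)") & (mat.cells["row_combination"] == "d1=2")
        ].iloc[0]
        assert cell["n_exposed"] == 14
        assert bool(cell["na"])

    def test_no_interaction_rows_consistent_across_columns(self, multiplicative_cohort, catalog):
        """Under multiplicative composition the within-stratum non-MHC OR does
        not depend on the MHC stratum; cells in one row should agree."""
        mat = combination_matrix(multiplicative_cohort, catalog)
        row = mat.cells[
            (mat.cells["row_combination"] == "d3=1") & (~mat.cells["na"])
            & (mat.cells["n_exposed"] >= 100)
        ]
        assert len(row) >= 3
        pairwise_z = []
        vals = row[["ln_or", "se_ln_or"]].to_numpy()
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                dz = (vals[i, 0] - vals[j, 0]) / math.hypot(vals[i, 1], vals[j, 1])
                pairwise_z.append(abs(dz))
        assert np.mean(np.asarray(pairwise_z) < 2.5) >= 0.9

    def test_band_binning(self):
        assert [z_band(z) for z in (0.5, -1.2, 2.9, -3.5, 7.0)] == [0, 1, 2, 3, 4]


class TestTransitionMatrix:
    def test_replacement_or_is_direct_genotype_or(self, study_cohort, catalog):
        tm = transition_matrix(study_cohort, catalog)
        ann = annotate_cohort(study_cohort, catalog)

        def geno_counts(code):
            sub = ann[ann["mhc_genotype"] == code]
            return (int((sub["status"] == "case").sum()), int((sub["status"] == "control").sum()))

        a_case, a_ctrl = geno_counts("(0,H+)")
        r_case, r_ctrl = geno_counts("(0,0)")
        direct = odds_ratio(ContingencyTable(a_case, a_ctrl, r_case, r_ctrl))
        assert tm.transition_ors[("0", "0", "H+")].or_value == pytest.approx(
            direct.or_value, rel=1e-12
        )

    def test_two_reading_identity_machine_precision(self, study_cohort, catalog):
        tm = transition_matrix(study_cohort, catalog)  # internal assert already ran
        ors = tm.transition_ors
        cell = tm.cells[
            (tm.cells["column_transition"] == "0->H+") & (tm.cells["row_transition"] == "c1->H+")
        ].iloc[0]
        reading1 = ors[("c1", "0", "H+")].ln_or - ors[("H+", "0", "H+")].ln_or
        reading2 = ors[("0", "c1", "H+")].ln_or - ors[("H+", "c1", "H+")].ln_or
        assert reading1 == pytest.approx(reading2, abs=1e-12)
        assert cell["ln_ratio"] == pytest.approx(reading1, abs=1e-12)

    def test_lower_triangle_only(self, study_cohort, catalog):
        tm = transition_matrix(study_cohort, catalog)
        order = {f"{a.code}->{b.code}": i for i, (a, b) in enumerate(tm.transitions)}
        assert all(
            order[r] > order[c]
            for r, c in zip(tm.cells["row_transition"], tm.cells["column_transition"])
        )

    def test_no_interaction_cells_near_zero(self, multiplicative_cohort, catalog):
        """With exactly multiplicative haplotype effects every replacement OR
        is companion-independent, so the ln-ratios scatter around 0."""
        tm = transition_matrix(multiplicative_cohort, catalog)
        ok = tm.cells[~tm.cells["na"]]
        assert len(ok) >= 8
        assert np.mean(np.abs(ok["z"]) < 2.5) >= 0.8
        assert abs(np.median(ok["ln_ratio"])) < 0.2

    def test_interaction_cell_signs_match_calibration(self, catalog):
        """In the study-like preset the 0->H+ replacement is stronger beside
        c1 than beside H+, and stronger beside AP than beside H+ — both
        read from the canonical lower-triangle cells."""
        coh = simulate_cohort(study_like_config(seed=41))
        tm = transition_matrix(coh, catalog)
        cells = tm.cells.set_index(["column_transition", "row_transition"])
        # ln[OR(c1, 0->H+) / OR(H+, 0->H+)]: calibrated to ln(3.67/2.17) > 0
        assert cells.loc[("0->H+", "c1->H+"), "ln_ratio"] > 0
        # ln[OR(0, AP->H+) / OR(H+, AP->H+)] == ln[OR(AP,0->H+)/OR(H+,0->H+)]
        # by the two-reading identity: calibrated to ln(3.4/2.17) > 0
        assert cells.loc[("AP->H+", "0->H+"), "ln_ratio"] > 0

    def test_needs_two_groups(self, study_cohort, catalog):
        with pytest.raises(ValueError):
            transition_matrix(study_cohort, catalog, groups=[G.H_PLUS])
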