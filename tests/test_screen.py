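import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episcreen import screen, synthetic
from episcreen.config import RunConfig
from episcreen.io_formats import ExpressionMatrix, GeneAnnotation

from conftest import random_culture_matrix, random_tissue_matrix
from oracles import brute_cerebellum_pass, brute_culture_pass, brute_universe

CULTURES = list(synthetic.CULTURE_SAMPLES)
OTHERS = list(synthetic.OTHER_CULTURES)
TISSUES = list(synthetic.TISSUE_SAMPLES)
BRAIN = list(synthetic.BRAIN_OTHER_SAMPLES)
NON_BRAIN = list(synthetic.NON_BRAIN_SAMPLES)


def culture_matrix_from_rows(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index",
                                      columns=CULTURES, dtype=float),
        unit_tag="FPKM", group_map=dict(synthetic.CULTURE_GROUP_MAP))


def tissue_matrix_from_rows(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index",
                                      columns=TISSUES, dtype=float),
        unit_tag="TPM", group_map=dict(synthetic.TISSUE_GROUP_MAP))


class TestFilterGeneUniverse:
    def _annotation(self, biotypes: dict[str, str]) -> list[GeneAnnotation]:
        return [GeneAnnotation(g, "chr1", i * 1000, i * 1000 + 500, "+", bt)
                for i, (g, bt) in enumerate(biotypes.items())]

    def test_mito_gene_excluded_despite_high_expression(self):
        tissue = tissue_matrix_from_rows({"gM": [1000.0] * 52})
        culture = culture_matrix_from_rows({"gM": [1000.0] * 6})
        ann = self._annotation({"gM": "mito"})
        assert screen.filter_gene_universe(tissue, culture, ann) == []

    def test_noncoding_excluded_unless_whitelisted(self):
        tissue = tissue_matrix_from_rows({"gN": [10.0] * 52})
        culture = culture_matrix_from_rows({"gN": [10.0] * 6})
        ann = self._annotation({"gN": "ncRNA"})
        assert screen.filter_gene_universe(tissue, culture, ann) == []
        assert screen.filter_gene_universe(tissue, culture, ann,
                                           whitelist={"gN"}) == ["gN"]

    def test_tissue_floor_failure_excludes(self):
        tissue = tissue_matrix_from_rows({"g1": [0.5] * 52})
        culture = culture_matrix_from_rows({"g1": [10.0] * 6})
        ann = self._annotation({"g1": "protein_coding"})
        assert screen.filter_gene_universe(tissue, culture, ann) == []

    def test_empty_namespace_intersection_rejected(self):
        tissue = tissue_matrix_from_rows({"g1": [1.0] * 52})
        culture = culture_matrix_from_rows({"g2": [1.0] * 6})
        ann = self._annotation({"g1": "protein_coding"})
        with pytest.raises(ValueError, match="shared"):
            screen.filter_gene_universe(tissue, culture, ann)

    def test_matches_brute_force_on_random_fixture(self, rng):
        tissue = random_tissue_matrix(rng, 80)
        culture = random_culture_matrix(rng, 80)
        biotypes = rng.choice(["protein_coding", "ncRNA", "mito", "other"],
                              size=80, p=[0.6, 0.2, 0.1, 0.1])
        ann = self._annotation({f"g{i:05d}": str(b)
                                for i, b in enumerate(biotypes)})
        got = screen.filter_gene_universe(tissue, culture, ann)
        assert got == brute_universe(tissue, culture, ann)


class TestCultureCall:
    def test_ratio_exactly_at_threshold_passes(self):
        mat = culture_matrix_from_rows({"g1": [10, 2, 2, 2, 2, 2]})
        passed, calls = screen.call_culture_preferential(mat, "myoblast")
        assert passed == {"g1"}
        assert calls["g1"].ratio == pytest.approx(5.0)

    def test_floor_failure(self):
        mat = culture_matrix_from_rows({"g1": [0.9, 0, 0, 0, 0, 0]})
        passed, calls = screen.call_culture_preferential(mat, "myoblast")
        assert passed == set()
        assert calls["g1"].ratio == math.inf

    def test_zero_denominator_with_floor_passes(self):
        mat = culture_matrix_from_rows({"g1": [3, 0, 0, 0, 0, 0]})
        passed, calls = screen.call_culture_preferential(mat, "myoblast")
        assert passed == {"g1"}
        assert calls["g1"].ratio == math.inf

    def test_missing_target_rejected(self):
        mat = culture_matrix_from_rows({"g1": [1] * 6})
        with pytest.raises(ValueError, match="absent"):
            screen.call_culture_preferential(mat, "HeLa")

    def test_matches_brute_force(self, culture_matrix):
        passed, _ = screen.call_culture_preferential(culture_matrix,
                                                     "myoblast")
        for g in culture_matrix.gene_ids:
            assert (g in passed) == brute_culture_pass(
                culture_matrix.values.loc[g], "myoblast", OTHERS)

    def test_passed_calls_satisfy_their_inequality(self, culture_matrix):
        cfg = RunConfig()
        _, calls = screen.call_culture_preferential(culture_matrix, "myoblast",
                                                    cfg)
        for c in calls.values():
            if c.passed:
                assert c.numerator >= cfg.expression_floor
                assert c.ratio >= cfg.ratio_threshold


class TestCerebellumCall:
    def _row(self, cbl, brain, nonbrain):
        return [cbl] + list(brain) + list(nonbrain)

    def test_both_ratios_exactly_at_threshold_pass(self):
        # dyadic values keep both ratios exactly 5.0 in float arithmetic
        mat = tissue_matrix_from_rows(
            {"g1": self._row(1.25, [0.25] * 10, [0.25] * 41)})
        passed, calls = screen.call_cerebellum_preferential(mat)
        assert passed == {"g1"}
        assert not calls["g1"].rescue_applied

    def test_zero_denominator_rescue(self):
        mat = tissue_matrix_from_rows(
            {"g1": self._row(8.0, [1.0] * 10, [0.0] * 41)})
        passed, calls = screen.call_cerebellum_preferential(mat)
        assert passed == {"g1"}
        assert calls["g1"].rescue_applied

    def test_rescue_denied_when_not_tissue_wide_maximum(self):
        row = self._row(8.0, [9.0] + [0.5] * 9, [0.0] * 41)
        mat = tissue_matrix_from_rows({"g1": row})
        passed, _ = screen.call_cerebellum_preferential(mat)
        assert passed == set()

    def test_wrong_group_cardinalities_rejected(self):
        values = pd.DataFrame([[1.0, 1.0]], index=["g1"],
                              columns=["cerebellum", "cortex"])
        mat = ExpressionMatrix(values=values, unit_tag="TPM",
                               group_map={"cerebellum": "cerebellum",
                                          "cortex": "brain_other"})
        with pytest.raises(ValueError, match="cardinalities"):
            screen.call_cerebellum_preferential(mat)

    def test_matches_brute_force(self, tissue_matrix):
        passed, _ = screen.call_cerebellum_preferential(tissue_matrix)
        for g in tissue_matrix.gene_ids:
            assert (g in passed) == brute_cerebellum_pass(
                tissue_matrix.values.loc[g], "cerebellum", BRAIN, NON_BRAIN)

    def test_brain_central_tendency_is_configurable(self):
        # median of the 10 other brain regions passes, mean does not
        brain = [0.1] * 5 + [0.3] + [10.0] * 4
        mat = tissue_matrix_from_rows({"g1": self._row(2.0, brain, [0.1] * 41)})
        med_cfg = RunConfig(brain_central_tendency="median")
        mean_cfg = RunConfig(brain_central_tendency="mean")
        assert screen.call_cerebellum_preferential(mat, med_cfg)[0] == {"g1"}
        assert screen.call_cerebellum_preferential(mat, mean_cfg)[0] == set()


class TestIntersectAndOverlap:
    def test_constructed_sizes(self):
        a = {f"m{i}" for i in range(402)} | {f"d{i}" for i in range(20)}
        b = {f"c{i}" for i in range(219)} | {f"d{i}" for i in range(20)}
        assert len(a) == 422 and len(b) == 239
        dual = screen.intersect_dual(a, b)
        assert len(dual) == 20
        assert dual == sorted(dual)

    def test_disjoint(self):
        assert screen.intersect_dual({"a"}, {"b"}) == []

    def test_random_matches_membership_scan(self, rng):
        a = {f"g{i}" for i in rng.integers(0, 200, size=80)}
        b = {f"g{i}" for i in rng.integers(0, 200, size=80)}
        assert screen.intersect_dual(a, b) == sorted(
            g for g in a if g in b)

    def test_overlap_matrix_with_planted_genes(self):
        rows = {}
        for i in range(3):  # ESC-preferential genes also in the cbl set
            rows[f"x{i}"] = [1, 50, 1, 1, 1, 1]
        rows["y0"] = [50, 1, 1, 1, 1, 1]  # myoblast-preferential, not in cbl
        mat = culture_matrix_from_rows(rows)
        table = screen.overlap_matrix(mat, cbl_set={"x0", "x1", "x2"})
        esc = table.set_index("culture").loc["ESC"]
        assert esc["n_preferential"] == 3
        assert esc["n_overlap_cbl"] == 3
        myob = table.set_index("culture").loc["myoblast"]
        assert myob["n_preferential"] == 1
        assert myob["n_overlap_cbl"] == 0

    def test_overlap_matrix_empty_cbl_set(self, culture_matrix):
        table = screen.overlap_matrix(culture_matrix, cbl_set=set())
        assert (table["n_overlap_cbl"] == 0).all()

    def test_overlap_matrix_matches_brute_force(self, culture_matrix, rng):
        cbl = {f"g{i:05d}" for i in rng.integers(0, 100, size=40)}
        table = screen.overlap_matrix(culture_matrix, cbl_set=cbl)
        for row in table.itertuples():
            others = [c for c in CULTURES if c != row.culture]
            pref = {g for g in culture_matrix.gene_ids
                    if brute_culture_pass(culture_matrix.values.loc[g],
                                          row.culture, others)}
            assert row.n_preferential == len(pref)
            assert row.n_overlap_cbl == len(pref & cbl)

    def test_intersection_bounded_by_set_sizes(self, culture_matrix, rng):
        cbl = {f"g{i:05d}" for i in rng.integers(0, 100, size=30)}
        table = screen.overlap_matrix(culture_matrix, cbl_set=cbl)
        assert (table["n_overlap_cbl"]
                <= table["n_preferential"].clip(upper=len(cbl))).all()


@st.composite
def expression_rows(draw, n_cols):
    vals = draw(st.lists(
        st.floats(min_value=0, max_value=100, allow_nan=False),
        min_size=n_cols, max_size=n_cols))
    return vals


class TestThresholdMonotonicity:
    @given(row=expression_rows(6),
           r_low=st.floats(1.5, 5), r_extra=st.floats(0, 10))
    @settings(max_examples=60, deadline=None)
    def test_raising_ratio_never_adds_genes(self, row, r_low, r_extra):
        mat = culture_matrix_from_rows({"g1": row})
        low, _ = screen.call_culture_preferential(
            mat, "myoblast", RunConfig(ratio_threshold=r_low))
        high, _ = screen.call_culture_preferential(
            mat, "myoblast", RunConfig(ratio_threshold=r_low + r_extra))
        assert high <= low

    @given(row=expression_rows(6),
           e_low=st.floats(0.1, 2), e_extra=st.floats(0, 5))
    @settings(max_examples=60, deadline=None)
    def test_lowering_floor_never_removes_genes(self, row, e_low, e_extra):
        mat = culture_matrix_from_rows({"g1": row})
        low, _ = screen.call_culture_preferential(
            mat, "myoblast", RunConfig(expression_floor=e_low))
        high, _ = screen.call_culture_preferential(
            mat, "myoblast", RunConfig(expression_floor=e_low + e_extra))
        assert high <= low
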