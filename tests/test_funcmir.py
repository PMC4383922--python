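"""Criterion scores, composite classification and mature-arm selection."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirfunc import funcmir as fm
from mirfunc.errors import ValidationError
from mirfunc.mirbase_io import (
    Arm,
    ExpressionTable,
    MatureRecord,
    PrecursorRecord,
    PubmedMap,
)

PARAMS = fm.ScoringParams()


def make_table(counts: dict, sizes: dict) -> ExpressionTable:
    experiments = list(sizes)
    df = pd.DataFrame(
        {e: {m: counts.get(m, {}).get(e, 0) for m in counts} for e in experiments},
        dtype="int64",
    )
    if df.empty:
        df = pd.DataFrame({e: pd.Series(dtype="int64") for e in experiments})
    return ExpressionTable(counts=df, library_sizes=pd.Series(sizes, dtype="int64"))


def mature(name, seq, arm=Arm.UNKNOWN, mid=None):
    return MatureRecord(
        id=mid or name, name=name, species=name.split("-")[0], sequence=seq, arm=arm
    )


SEQ22 = "UGUGCAAAUCCAUGCAAAACUG"  # 22 nt


class TestCriterionBrackets:
    @pytest.mark.parametrize(
        "n,expected", [(0, 0), (1, 0), (2, 1), (3, 2), (4, 3), (17, 3)]
    )
    def test_pubmed_brackets(self, n, expected):
        assert fm.pubmed_score(n, PARAMS) == expected

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 1), (2, 2), (3, 2)])
    def test_conservation_brackets(self, n, expected):
        assert fm.conservation_score(n, PARAMS) == expected

    @pytest.mark.parametrize(
        "rpm,expected",
        [(0.0, 0), (0.2, 0), (0.999, 0), (1.0, 1), (5.0, 1), (10.0, 1), (10.001, 2), (15.0, 2)],
    )
    def test_expression_brackets_inclusive_low_strict_high(self, rpm, expected):
        assert fm.expression_score(rpm, PARAMS) == expected

    @pytest.mark.parametrize("flag,expected", [(True, 1), (False, 0)])
    def test_mirbase_flag(self, flag, expected):
        assert fm.mirbase_score(flag) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fm.pubmed_score(-1, PARAMS)
        with pytest.raises(ValidationError):
            fm.conservation_score(-1, PARAMS)
        with pytest.raises(ValidationError):
            fm.expression_score(-0.5, PARAMS)


class TestOrthology:
    def test_full_identity_implies_ortholog(self):
        q = mature("hsa-miR-a-5p", SEQ22)
        foreign = {"mmu": [mature("mmu-miR-a-5p", SEQ22)]}
        assert fm.find_orthologs(q, foreign, PARAMS) == {"mmu"}

    def test_19nt_prefix_with_divergent_3prime_end(self):
        q = mature("hsa-miR-a-5p", SEQ22[:19] + "AAA")
        foreign = {"rno": [mature("rno-miR-a-5p", SEQ22[:19] + "GGG")]}
        assert fm.find_orthologs(q, foreign, PARAMS) == {"rno"}

    def test_mismatch_within_prefix_is_not_ortholog(self):
        other = SEQ22[:4] + ("A" if SEQ22[4] != "A" else "C") + SEQ22[5:]
        q = mature("hsa-miR-a-5p", SEQ22)
        assert fm.find_orthologs(q, {"mmu": [mature("mmu-miR-a-5p", other)]}, PARAMS) == set()

    def test_own_species_excluded(self):
        q = mature("hsa-miR-a-5p", SEQ22)
        foreign = {"hsa": [mature("hsa-miR-b-5p", SEQ22)]}
        assert fm.find_orthologs(q, foreign, PARAMS) == set()

    def test_empty_query_rejected(self):
        q = MatureRecord.__new__(MatureRecord)  # bypass length check
        q.id = q.name = "hsa-miR-x"
        q.species, q.sequence, q.arm = "hsa", "", Arm.UNKNOWN
        with pytest.raises(ValidationError):
            fm.find_orthologs(q, {}, PARAMS)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.text(alphabet="ACGU", min_size=17, max_size=30),
        b=st.text(alphabet="ACGU", min_size=17, max_size=30),
    )
    def test_prefix_relation_symmetric(self, a, b):
        ma, mb = mature("hsa-miR-a-5p", a), mature("mmu-miR-b-5p", b)
        assert (fm.find_orthologs(ma, {"mmu": [mb]}, PARAMS) == {"mmu"}) == (
            fm.find_orthologs(mb, {"hsa": [ma]}, PARAMS) == {"hsa"}
        )


class TestRpm:
    def test_unit_scale(self):
        t = make_table({"m1": {"e1": 10}}, {"e1": 1_000_000})
        assert fm.pooled_rpm(t, "m1") == 10.0

    def test_pooled_aggregation_hand_computed(self):
        t = make_table({"m1": {"e1": 5, "e2": 5}}, {"e1": 500_000, "e2": 1_500_000})
        assert fm.pooled_rpm(t, "m1") == pytest.approx(5.0)

    def test_absent_mature_is_zero(self):
        t = make_table({"m1": {"e1": 10}}, {"e1": 1_000_000})
        assert fm.pooled_rpm(t, "nope") == 0.0

    def test_zero_total_library_rejected(self):
        t = make_table({}, {})
        with pytest.raises(ValidationError):
            fm.pooled_rpm(t, "m1")

    def test_mean_aggregation_differs_from_pooled(self):
        t = make_table({"m1": {"e1": 5, "e2": 5}}, {"e1": 500_000, "e2": 1_500_000})
        assert fm.mean_rpm(t, "m1") == pytest.approx((10.0 + 10.0 / 3) / 2)


def make_scored_setup(n_pmids, n_species, rpm, highconf):
    prefix = SEQ22[:19]
    arms = [mature("hsa-miR-f-5p", prefix + "AAA", Arm.FIVE_P, mid="MIMAT1")]
    foreign = [
        mature(f"{sp}-miR-f-5p", prefix + "GGG", Arm.FIVE_P, mid=f"X{sp}")
        for sp in ("mmu", "rno", "cfa", "gga")[:n_species]
    ]
    prec = PrecursorRecord(
        id="MI1", name="hsa-mir-f", species="hsa", sequence=prefix * 4,
        mature_ids=["MIMAT1"], high_confidence=highconf,
    )
    pubmed = PubmedMap({"hsa-mir-f": set(range(1, n_pmids + 1))} if n_pmids else {})
    table = make_table({"hsa-miR-f-5p": {"e1": int(rpm)}}, {"e1": 1_000_000})
    orthology = fm.build_orthology_map(arms + foreign, PARAMS)
    matures_by_id = {m.id: m for m in arms + foreign}
    return prec, pubmed, orthology, table, matures_by_id


class TestScorePrecursor:
    @pytest.mark.parametrize(
        "n_pmids,n_species,rpm,highconf,expected",
        [
            (4, 2, 15, True, (3, 2, 2, 1)),
            (0, 0, 0, False, (0, 0, 0, 0)),
            (2, 1, 0.5, False, (1, 1, 0, 0)),
        ],
    )
    def test_examples(self, n_pmids, n_species, rpm, highconf, expected):
        prec, pubmed, orthology, table, by_id = make_scored_setup(
            n_pmids, n_species, rpm, highconf
        )
        scores = fm.score_precursor(prec, pubmed, orthology, table, PARAMS, by_id)
        assert (scores.pubmed, scores.conservation, scores.expression, scores.mirbase) == expected
        assert scores.composite == sum(expected)

    def test_precursor_without_arms_rejected(self):
        prec = PrecursorRecord(id="MI1", name="hsa-mir-f", species="hsa", sequence="ACGU" * 10)
        with pytest.raises(ValidationError, match="no mature arms"):
            fm.score_precursor(prec, PubmedMap(), {}, make_table({}, {"e1": 10}), PARAMS)


class TestClassification:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            (fm.CriterionScores(1, 1, 1, 0), True),  # composite 3
            (fm.CriterionScores(1, 1, 0, 0), False),  # composite 2
            (fm.CriterionScores(3, 2, 2, 1), True),  # composite 8
        ],
    )
    def test_threshold_of_three(self, scores, expected):
        assert fm.classify_functional(scores, PARAMS) is expected

    def test_minimum_functional_composite_is_three(self):
        achievable = sorted(
            {
                fm.CriterionScores(p, c, e, m).composite
                for p in range(4)
                for c in range(3)
                for e in range(3)
                for m in range(2)
            }
        )
        assert achievable == list(range(9))
        functional = [
            comp
            for comp in achievable
            for p in range(4)
            for c in range(3)
            for e in range(3)
            for m in range(2)
            if fm.CriterionScores(p, c, e, m).composite == comp
            and fm.classify_functional(fm.CriterionScores(p, c, e, m), PARAMS)
        ]
        assert min(functional) == 3


class TestMatureSelection:
    def make_prec(self, arms):
        by_id = {
            mid: MatureRecord(
                id=mid, name=mid, species="hsa",
                sequence=SEQ22, arm=arm,
            )
            for mid, arm in arms
        }
        prec = PrecursorRecord(
            id="MI1", name="hsa-mir-f", species="hsa", sequence=SEQ22 * 3,
            mature_ids=[mid for mid, _ in arms],
        )
        return prec, by_id

    def test_ten_percent_boundary_inclusive(self):
        prec, by_id = self.make_prec([("hsa-miR-f-5p", Arm.FIVE_P), ("hsa-miR-f-3p", Arm.THREE_P)])
        dom, sec = fm.select_functional_matures(
            prec, {"hsa-miR-f-5p": 100.0, "hsa-miR-f-3p": 10.0}, PARAMS, by_id
        )
        assert (dom, sec) == ("hsa-miR-f-5p", "hsa-miR-f-3p")

    def test_five_rpm_floor_excludes_secondary(self):
        prec, by_id = self.make_prec([("hsa-miR-f-5p", Arm.FIVE_P), ("hsa-miR-f-3p", Arm.THREE_P)])
        dom, sec = fm.select_functional_matures(
            prec, {"hsa-miR-f-5p": 100.0, "hsa-miR-f-3p": 4.0}, PARAMS, by_id
        )
        assert (dom, sec) == ("hsa-miR-f-5p", None)

    def test_single_arm_dominant_no_secondary(self):
        prec, by_id = self.make_prec([("hsa-miR-f-5p", Arm.FIVE_P)])
        assert fm.select_functional_matures(prec, {"hsa-miR-f-5p": 2.0}, PARAMS, by_id) == (
            "hsa-miR-f-5p", None,
        )

    def test_tie_prefers_5p_arm(self):
        prec, by_id = self.make_prec([("hsa-miR-f-3p", Arm.THREE_P), ("hsa-miR-f-5p", Arm.FIVE_P)])
        dom, _ = fm.select_functional_matures(
            prec, {"hsa-miR-f-5p": 7.0, "hsa-miR-f-3p": 7.0}, PARAMS, by_id
        )
        assert dom == "hsa-miR-f-5p"

    def test_dominant_rpm_below_floor_still_selected(self):
        prec, by_id = self.make_prec([("hsa-miR-f-5p", Arm.FIVE_P), ("hsa-miR-f-3p", Arm.THREE_P)])
        dom, sec = fm.select_functional_matures(
            prec, {"hsa-miR-f-5p": 0.0, "hsa-miR-f-3p": 0.0}, PARAMS, by_id
        )
        assert dom == "hsa-miR-f-5p" and sec is None  # 0 rpm fails the 5-RPM floor


class TestRequiredCriteria:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            (fm.CriterionScores(3, 0, 0, 0), {"pubmed"}),
            (fm.CriterionScores(3, 2, 2, 1), set()),
            (fm.CriterionScores(1, 1, 0, 0), set()),  # not functional
            (fm.CriterionScores(1, 1, 1, 0), {"pubmed", "conservation", "expression"}),
        ],
    )
    def test_removal_analysis(self, scores, expected):
        assert fm.required_criteria(scores, PARAMS) == frozenset(expected)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.integers(0, 3), c=st.integers(0, 2), e=st.integers(0, 2), m=st.integers(0, 1)
    )
    def test_required_subset_of_nonzero(self, p, c, e, m):
        scores = fm.CriterionScores(p, c, e, m)
        req = fm.required_criteria(scores, PARAMS)
        nonzero = {crit for crit in fm.CRITERIA if getattr(scores, crit) > 0}
        assert req <= nonzero
        for crit in fm.CRITERIA:
            assert scores.composite - getattr(scores, crit) <= scores.composite


@pytest.mark.parametrize(
    "scores,expected",
    [(fm.CriterionScores(3, 2, 2, 1), 4), (fm.CriterionScores(0, 0, 0, 0), 0), (fm.CriterionScores(1, 0, 2, 0), 2)],
)
def test_n_supporting_criteria(scores, expected):
    assert fm.n_supporting_criteria(scores) == expected


class TestMonotonicity:
    @settings(derandomize=True, max_examples=100)
    @given(a=st.integers(0, 50), b=st.integers(0, 50))
    def test_pubmed_and_conservation_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert fm.pubmed_score(lo, PARAMS) <= fm.pubmed_score(hi, PARAMS)
        assert fm.conservation_score(lo, PARAMS) <= fm.conservation_score(hi, PARAMS)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(0, 1e4, allow_nan=False), b=st.floats(0, 1e4, allow_nan=False)
    )
    def test_expression_monotone_in_rpm(self, a, b):
        lo, hi = sorted((a, b))
        assert fm.expression_score(lo, PARAMS) <= fm.expression_score(hi, PARAMS)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.integers(0, 3), c=st.integers(0, 2), e=st.integers(0, 2), m=st.integers(0, 1)
    )
    def test_composite_bounds_and_classifier_monotone(self, p, c, e, m):
        scores = fm.CriterionScores(p, c, e, m)
        assert 0 <= scores.composite <= 8
        if fm.classify_functional(scores, PARAMS):
            bigger = fm.CriterionScores(min(3, p + 1), c, e, m)
            assert fm.classify_functional(bigger, PARAMS)
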