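import numpy as np
import pytest
from scipy import stats
from scipy.stats import chi2_contingency

from scolioclass import (
    ContractError,
    DegenerateTableError,
    build_concordance,
    concordance_charts,
    expected_sagittal_categories,
    expected_vertical_categories,
    load_reference_concordance,
    pearson_chi_square,
    percent_agreement,
    read_contingency,
    validate_patient,
    write_contingency,
)
from scolioclass.classify import NA, Classification
from scolioclass.indices import IndexSet, StdVector
from scolioclass.io import LenkeRecord
from scolioclass.lenke import ConcordanceTable


def _cls(patient_id="1", vertical="Thoraco-lumbar", sagittal="Normal spine"):
    severity = "No scoliosis" if vertical == NA else "Slightly significant"
    side = NA if vertical == NA else "Left-sided"
    return Classification(
        patient_id=patient_id,
        std=StdVector(1, 2, 3, 4),
        indices=IndexSet(s=0.1, v=0.0, kl=0.1, m_t=20.0, m_l=-20.0),
        severity=severity, side=side, vertical=vertical, sagittal=sagittal,
        description="", apexes=(),
    )


def _brute_force_chi2(counts):
    """Independent oracle: explicit loops over cells."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i, :].sum() * counts[:, j].sum() / n
            stat += (counts[i, j] - e) ** 2 / e
    return stat


class TestExpectedCategories:
    @pytest.mark.parametrize(
        "lenke_type, expected",
        [
            ("1", {"Thoracic", "Mainly thoracic"}),
            ("2", {"Thoracic", "Mainly thoracic"}),
            ("3", {"Mainly thoracic", "Thoraco-lumbar"}),
            ("4", {"Mainly thoracic", "Thoraco-lumbar"}),
            ("5", {"Lumbar", "Mainly lumbar", "Thoraco-lumbar"}),
            ("6", {"Thoraco-lumbar", "Mainly lumbar"}),
            ("Normal", {NA}),
        ],
    )
    def test_vertical_map(self, lenke_type, expected):
        assert expected_vertical_categories(lenke_type) == expected

    @pytest.mark.parametrize(
        "modifier, expected",
        [
            ("+", {"Significant kyphosis", "Extreme kyphosis"}),
            ("-", set()),
            ("−", set()),  # Unicode minus
            ("N", {"Normal spine", "Slight kyphosis", "Slight lordosis"}),
        ],
    )
    def test_sagittal_map(self, modifier, expected):
        assert expected_sagittal_categories(modifier) == expected

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ContractError):
            expected_vertical_categories("7")
        with pytest.raises(ContractError):
            expected_sagittal_categories("?")


class TestValidatePatient:
    def test_transitional_curve_validates_type6(self):
        res = validate_patient(_cls(vertical="Thoraco-lumbar"),
                               LenkeRecord("1", "6", "B", "N"))
        assert res.v_validated and res.v_group == "6"

    def test_transitional_curve_fails_type1(self):
        res = validate_patient(_cls(vertical="Thoraco-lumbar"),
                               LenkeRecord("1", "1", "B", "N"))
        assert not res.v_validated

    def test_no_scoliosis_output_validates_lenke_normal(self):
        res = validate_patient(_cls(vertical=NA), LenkeRecord("1", "Normal"))
        assert res.v_validated

    def test_lordotic_output_goes_to_slash_group(self):
        res = validate_patient(_cls(sagittal="Significant lordosis"),
                               LenkeRecord("1", "3", "B", "N"))
        assert res.kl_group == "/" and not res.kl_validated

    def test_minus_modifier_never_validates(self):
        res = validate_patient(_cls(sagittal="Slight kyphosis"),
                               LenkeRecord("1", "3", "B", "-"))
        assert res.kl_group == "-" and not res.kl_validated

    def test_lenke_normal_scored_against_normal_kyphosis_band(self):
        res = validate_patient(_cls(sagittal="Slight kyphosis"), LenkeRecord("1", "Normal"))
        assert res.kl_group == "N" and res.kl_validated

    def test_patient_id_mismatch_rejected(self):
        with pytest.raises(ContractError):
            validate_patient(_cls(patient_id="a"), LenkeRecord("b", "Normal"))


class TestBuildConcordance:
    def test_single_record(self):
        t = build_concordance([("3", True)])
        assert t.rows == ("3",) and t.validated == (1,) and t.not_validated == (0,)

    def test_order_invariance(self):
        recs = [("1", True), ("2", False), ("1", False), ("2", True), ("1", True)]
        a = build_concordance(recs, row_order=["1", "2"])
        b = build_concordance(list(reversed(recs)), row_order=["1", "2"])
        assert a == b

    def test_reference_totals_reaggregate(self):
        """Expanding the bundled vertical table to per-patient records and
        re-aggregating returns the same 68 validated / 26 not."""
        table = load_reference_concordance("vertical")
        records = []
        for g, v, n in zip(table.rows, table.validated, table.not_validated):
            records += [(g, True)] * v + [(g, False)] * n
        again = build_concordance(records, row_order=table.rows)
        assert again == table
        assert sum(again.validated) == 68 and sum(again.not_validated) == 26


class TestChiSquare:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            r = int(rng.integers(2, 7))
            counts = rng.integers(1, 40, size=(r, 2))
            table = ConcordanceTable(
                rows=tuple(str(i) for i in range(r)),
                validated=tuple(int(c) for c in counts[:, 0]),
                not_validated=tuple(int(c) for c in counts[:, 1]),
            )
            res = pearson_chi_square(table)
            assert res.statistic == pytest.approx(_brute_force_chi2(counts), abs=1e-9)
            ref_stat, ref_p, ref_df, _ = chi2_contingency(counts, correction=False)
            assert res.statistic == pytest.approx(ref_stat, abs=1e-9)
            assert res.df == ref_df
            assert res.p_value == pytest.approx(ref_p, abs=1e-12)

    def test_homogeneous_table_scores_zero(self):
        t = ConcordanceTable(("a", "b", "c"), (10, 20, 5), (10, 20, 5))
        assert pearson_chi_square(t).statistic == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance_and_count_scaling(self):
        t = ConcordanceTable(("a", "b", "c"), (3, 9, 1), (5, 2, 8))
        perm = ConcordanceTable(("c", "a", "b"), (1, 3, 9), (8, 5, 2))
        assert pearson_chi_square(t).statistic == pytest.approx(
            pearson_chi_square(perm).statistic, abs=1e-12
        )
        k = 7
        scaled = ConcordanceTable(("a", "b", "c"), (21, 63, 7), (35, 14, 56))
        assert pearson_chi_square(scaled).statistic == pytest.approx(
            k * pearson_chi_square(t).statistic, rel=1e-12
        )

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square(ConcordanceTable(("a", "b"), (3, 4), (0, 0)))


class TestAgreement:
    def test_reference_vertical_agreement(self):
        table = load_reference_concordance("vertical")
        assert percent_agreement(table) == pytest.approx(72.3, abs=0.05)

    def test_reference_sagittal_agreement(self):
        table = load_reference_concordance("sagittal")
        assert percent_agreement(table) == pytest.approx(68.09, abs=0.005)

    def test_all_validated_is_100(self):
        t = ConcordanceTable(("a", "b"), (4, 6), (0, 0))
        assert percent_agreement(t) == 100.0

    def test_bounds(self):
        t = ConcordanceTable(("a",), (3,), (7,))
        assert 0.0 <= percent_agreement(t) <= 100.0


class TestContingencyIO:
    def test_round_trip(self, tmp_path):
        t = load_reference_concordance("sagittal")
        p = tmp_path / "t.csv"
        write_contingency(t, p)
        assert read_contingency(p) == t

    def test_charts_written(self, tmp_path):
        paths = concordance_charts(load_reference_concordance("vertical"), tmp_path)
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)
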