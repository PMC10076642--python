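"""Case-series summarizer: bins, medians, vocabularies, fixture marginals."""

import random

import pytest

from pvsignal import (
    LiteratureCase,
    bin_onset,
    bin_relief,
    load_case_table,
    median_onset,
    reference_case_csv_path,
    reference_case_series,
    summarize_cases,
    summary_frame,
)
from pvsignal.cases import VocabularyError, dump_case_table, median_age, median_relief


class TestBins:
    @pytest.mark.parametrize("months,label", [
        (0.47, "<1"), (0.999, "<1"),
        (1.0, "1-3"), (2.9, "1-3"),
        (3.0, "3-6"),          # boundary resolves upward: half-open [3, 6)
        (5.99, "3-6"), (6.0, "6-12"), (12.0, "12-24"),
        (24.0, ">24"), (48.0, ">24"),
    ])
    def test_onset_half_open_bins(self, months, label):
        assert bin_onset(months) == label

    @pytest.mark.parametrize("weeks,label", [
        (1, "<2w"), (1.99, "<2w"), (2.0, "2-4w"), (3, "2-4w"),
        (4.0, ">4w"), (12, ">4w"),
    ])
    def test_relief_half_open_bins(self, weeks, label):
        assert bin_relief(weeks) == label

    @pytest.mark.parametrize("func", [bin_onset, bin_relief])
    def test_non_positive_rejected(self, func):
        with pytest.raises(ValueError):
            func(0)
        with pytest.raises(ValueError):
            func(-1)


class TestMedians:
    def test_odd_count(self):
        cases = [LiteratureCase(drug="secukinumab", onset_months=m) for m in (1, 2.9, 10)]
        assert median_onset(cases) == 2.9

    def test_even_count_averages_central_pair(self):
        cases = [LiteratureCase(drug="secukinumab", onset_months=m) for m in (1, 3)]
        assert median_onset(cases) == 2.0

    def test_missing_values_excluded(self):
        cases = [
            LiteratureCase(drug="secukinumab", onset_months=5),
            LiteratureCase(drug="secukinumab"),
        ]
        assert median_onset(cases) == 5

    def test_all_missing_is_na(self):
        assert median_onset([LiteratureCase(drug="secukinumab")]) is None


class TestVocabulary:
    def test_unknown_symptom_rejected(self):
        with pytest.raises(VocabularyError):
            LiteratureCase(drug="secukinumab", symptoms=frozenset({"hiccups"}))

    def test_unknown_drug_rejected(self):
        with pytest.raises(VocabularyError):
            LiteratureCase(drug="aspirin")

    def test_empty_symptom_set_rejected(self):
        with pytest.raises(ValueError, match="symptoms"):
            LiteratureCase(drug="secukinumab", symptoms=frozenset())

    def test_load_error_carries_line_number(self, tmp_path):
        path = reference_case_csv_path()
        lines = path.read_text().splitlines()
        lines[3] = lines[3].replace("secukinumab", "aspirin")
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(VocabularyError, match="line 3"):
            load_case_table(bad)


class TestSummaries:
    def test_empty_input_gives_empty_tables(self):
        assert summarize_cases([]) == []
        assert summary_frame([]).empty

    def test_permutation_invariance(self):
        cases = reference_case_series()
        shuffled = cases.copy()
        random.Random(3).shuffle(shuffled)
        assert summary_frame(cases).equals(summary_frame(shuffled))

    def test_exclusive_percentages_sum_to_100(self):
        frame = summary_frame(reference_case_series())
        exclusive = ("sex", "age_band", "region", "drug", "indication", "smoking",
                     "ibd_class", "therapy", "outcome", "relief_bin", "onset_bin")
        for var in exclusive:
            total = frame.loc[frame.variable == var, "percent"].sum()
            assert total == pytest.approx(100.0, abs=0.2), var

    def test_missing_fields_shrink_denominator_only(self):
        cases = [
            LiteratureCase(drug="secukinumab", wbc="elevated"),
            LiteratureCase(drug="ixekizumab"),  # wbc unreported
        ]
        frame = summary_frame(cases)
        wbc = frame[frame.variable == "wbc"]
        assert wbc["denominator"].eq(1).all()
        drug = frame[frame.variable == "drug"]
        assert drug["denominator"].eq(2).all()

    def test_single_case_percentages_are_100_for_present_fields(self):
        case = LiteratureCase(drug="secukinumab", sex="female", wbc="elevated",
                              therapy="corticosteroids")
        frame = summary_frame([case])
        for var, cat in (("drug", "secukinumab"), ("sex", "female"),
                         ("wbc", "elevated"), ("therapy", "corticosteroids")):
            row = frame[(frame.variable == var) & (frame.category == cat)]
            assert row["percent"].item() == 100.0


@pytest.fixture(scope="module")
def frame():
    return summary_frame(reference_case_series())


class TestReferenceSeries:
    """The shipped synthetic 34-case series reproduces the published marginals."""

    # every published count, keyed by (variable, category)
    EXPECTED_COUNTS = {
        ("data_resource", "case_report"): (25, 29),
        ("data_resource", "case_series"): (4, 29),
        ("sex", "female"): (17, 34), ("sex", "male"): (17, 34),
        ("age_band", "<=25"): (1, 34), ("age_band", "26-50"): (23, 34),
        ("age_band", "51-75"): (9, 34), ("age_band", ">=76"): (1, 34),
        ("region", "USA"): (11, 33), ("region", "Europe"): (13, 33),
        ("region", "Canada"): (6, 33), ("region", "Asia"): (2, 33),
        ("region", "other"): (1, 33),
        ("drug", "secukinumab"): (27, 34), ("drug", "ixekizumab"): (7, 34),
        ("preexisting_ibd", "pre-existing IBD"): (3, 34),
        ("preexisting_ibd", "new onset of IBD"): (31, 34),
        ("family_history_ibd", "family history of IBD"): (5, 34),
        ("indication", "PsO"): (20, 34), ("indication", "PsA"): (4, 34),
        ("indication", "PsO_and_PsA"): (3, 34), ("indication", "AS"): (7, 34),
        ("smoking", "yes"): (8, 34), ("smoking", "no"): (4, 34),
        ("smoking", "not_mentioned"): (22, 34),
        ("prior_tnf", "adalimumab"): (13, 24), ("prior_tnf", "etanercept"): (11, 24),
        ("onset_bin", "<1"): (5, 27), ("onset_bin", "1-3"): (9, 27),
        ("onset_bin", "3-6"): (7, 27), ("onset_bin", "6-12"): (3, 27),
        ("onset_bin", "12-24"): (2, 27), ("onset_bin", ">24"): (1, 27),
        ("ibd_class", "UC"): (13, 28), ("ibd_class", "CD"): (10, 28),
        ("ibd_class", "unclassified"): (5, 28),
        ("initial_symptoms", "diarrhea"): (30, 33),
        ("initial_symptoms", "bloody_diarrhea"): (17, 33),
        ("initial_symptoms", "abdominal_pain"): (19, 33),
        ("initial_symptoms", "fever"): (12, 33),
        ("initial_symptoms", "chills"): (4, 33),
        ("initial_symptoms", "nausea"): (4, 33),
        ("initial_symptoms", "weight_loss"): (5, 33),
        ("initial_symptoms", "asymptomatic"): (1, 33),
        ("wbc", "normal"): (1, 8), ("wbc", "elevated"): (7, 8),
        ("crp", "elevated"): (16, 16),
        ("esr", "normal"): (1, 7), ("esr", "elevated"): (6, 7),
        ("fecal_calprotectin", "elevated"): (4, 4),
        ("ct_findings", "normal"): (2, 10),
        ("ct_findings", "bowel_wall_thickening"): (5, 10),
        ("ct_findings", "pancolitis"): (2, 10),
        ("ct_findings", "colon_perforated"): (1, 10),
        ("colonoscopy_findings", "edematous"): (5, 28),
        ("colonoscopy_findings", "erythematous_mucosa"): (6, 28),
        ("colonoscopy_findings", "hemorrhagic"): (3, 28),
        ("colonoscopy_findings", "friable_mucosa"): (4, 28),
        ("colonoscopy_findings", "absent_vascular_pattern"): (4, 28),
        ("colonoscopy_findings", "superficial_ulceration"): (6, 28),
        ("colonoscopy_findings", "deep_ulcerations"): (13, 28),
        ("colonoscopy_findings", "active_inflammation"): (8, 28),
        ("histopathology_findings", "cryptitis"): (8, 25),
        ("histopathology_findings", "crypt_abscesses"): (8, 25),
        ("histopathology_findings", "granulomatous_lesions"): (7, 25),
        ("histopathology_findings", "chronic_inflammation"): (11, 25),
        ("therapy", "none"): (1, 31), ("therapy", "corticosteroids"): (10, 31),
        ("therapy", "tnf_antagonist"): (6, 31), ("therapy", "ustekinumab"): (2, 31),
        ("therapy", "five_asa"): (1, 31),
        ("therapy", "corticosteroids_plus_tnf_antagonist"): (6, 31),
        ("therapy", "corticosteroids_plus_five_asa"): (4, 31),
        ("therapy", "corticosteroids_plus_ustekinumab"): (1, 31),
        ("outcome", "recovered"): (27, 29), ("outcome", "relapse"): (2, 29),
        ("relief_bin", "<2w"): (3, 15), ("relief_bin", "2-4w"): (7, 15),
        ("relief_bin", ">4w"): (5, 15),
    }

    def test_every_published_count_reproduced(self, frame):
        got = {
            (r.variable, r.category): (r.count, r.denominator)
            for r in frame.itertuples()
        }
        mismatches = {
            key: (want, got.get(key))
            for key, want in self.EXPECTED_COUNTS.items()
            if got.get(key) != want
        }
        assert not mismatches

    def test_headline_percentages(self, frame):
        idx = {(r.variable, r.category): r.percent for r in frame.itertuples()}
        assert idx[("initial_symptoms", "diarrhea")] == 90.9
        assert idx[("drug", "secukinumab")] == 79.4
        assert idx[("preexisting_ibd", "new onset of IBD")] == 91.2

    def test_medians_and_ranges(self):
        cases = reference_case_series()
        assert median_age(cases) == 42
        assert median_onset(cases) == 2.9
        onsets = [c.onset_months for c in cases if c.onset_months is not None]
        ages = [c.age_years for c in cases if c.age_years is not None]
        assert (min(onsets), max(onsets)) == (0.47, 48.0)
        assert (min(ages), max(ages)) == (19, 76)
        # the half-open relief bins force the median below 4 weeks
        assert median_relief(cases) == pytest.approx(3.3)

    def test_bundled_csv_round_trips(self, tmp_path):
        cases = load_case_table(reference_case_csv_path())
        assert cases == reference_case_series()
        out = tmp_path / "copy.csv"
        dump_case_table(cases, out)
        assert load_case_table(out) == cases
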