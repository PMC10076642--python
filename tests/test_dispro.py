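"""ROR machinery: Woolf CI oracle values, algebraic properties, tallies."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import (
    DEFAULT_GROUPS,
    IL17_DICTIONARY,
    ContingencyTable,
    EventGroup,
    PlantedAssociation,
    RorResult,
    build_contingency,
    compute_ror,
    deduplicate,
    flag_signal,
    generate_reports,
    proportion_of_reports,
    run_disproportionality,
    study_config,
)
from pvsignal.faers import ConfigError

from conftest import make_report

cells = st.integers(min_value=1, max_value=500)


def brute_force_contingency(reports, active, dictionary, pts):
    """Independent oracle: classify every (report, distinct PT) pair one by one."""
    target = {p.strip().lower() for p in pts}
    a = b = c = d = 0
    for r in reports:
        exposed = any(
            e.role == "PS" and dictionary.match(e.verbatim_name) == active
            for e in r.drugs
        )
        for pt in {p.strip().lower() for p in r.reaction_pts}:
            if exposed and pt in target:
                a += 1
            elif exposed:
                b += 1
            elif pt in target:
                c += 1
            else:
                d += 1
    return a, b, c, d


class TestComputeRor:
    def test_woolf_interval_against_frozen_oracle(self):
        # hand-computed: se = sqrt(1/20+1/80+1/10+1/90) = 0.41666667 exactly,
        # CI = 2.25 * exp(-/+ 1.96 * se)
        res = compute_ror(ContingencyTable(20, 80, 10, 90))
        assert res.ror == pytest.approx(2.25)
        assert res.ci_low == pytest.approx(0.99427997, rel=1e-6)
        assert res.ci_high == pytest.approx(5.09162424, rel=1e-6)
        assert res.n_cases == 20

    def test_balanced_table_is_unity_with_log_symmetric_ci(self):
        res = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert res.ror == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        ContingencyTable(0, 5, 5, 5),
        ContingencyTable(5, 0, 5, 5),
        ContingencyTable(5, 5, 0, 5),
        ContingencyTable(5, 5, 5, 0),
    ])
    def test_any_zero_cell_is_na(self, table):
        res = compute_ror(table)
        assert res.ror is None and res.ci_low is None and res.ci_high is None
        assert res.signal is False

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(-1, 1, 1, 1)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(deadline=None, max_examples=200)
    def test_row_swap_inverts_and_ci_contains_point(self, a, b, c, d):
        res = compute_ror(ContingencyTable(a, b, c, d))
        inv = compute_ror(ContingencyTable(c, d, a, b))
        assert res.ror * inv.ror == pytest.approx(1.0, rel=1e-9)
        assert res.ci_low <= res.ror <= res.ci_high
        assert (res.ror == pytest.approx(1.0, rel=1e-12)) == (a * d == b * c)

    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 10))
    @settings(deadline=None, max_examples=100)
    def test_scaling_cells_up_narrows_log_ci(self, a, b, c, d, k):
        # point estimate is scale-invariant; more data must not widen the CI
        small = compute_ror(ContingencyTable(a, b, c, d))
        big = compute_ror(ContingencyTable(k * a, k * b, k * c, k * d))
        assert big.ror == pytest.approx(small.ror, rel=1e-9)
        w_small = math.log(small.ci_high) - math.log(small.ci_low)
        w_big = math.log(big.ci_high) - math.log(big.ci_low)
        assert w_big <= w_small + 1e-12


class TestSignalRule:
    @pytest.mark.parametrize("ror,lo,hi,n,expected", [
        (2.13, 1.96, 2.30, 611, True),   # strong class-wide signal
        (1.48, 0.48, 4.60, 3, False),    # CI crosses 1
        (3.00, 1.01, 9.00, 2, False),    # fewer than three cases
        (3.00, 1.01, 9.00, 3, True),     # boundary case count
        (2.00, 1.00, 4.00, 10, False),   # lower limit must exceed 1 strictly
        (None, None, None, 0, False),    # undefined CI never signals
    ])
    def test_truth_table(self, ror, lo, hi, n, expected):
        assert flag_signal(RorResult(ror, lo, hi, n_cases=n, signal=False)) is expected


class TestProportionOfReports:
    @pytest.mark.parametrize("count,total,mode,expected", [
        (611, 44688, "half_up", 1.37),
        (611, 44688, "truncate", 1.36),
        (160, 24406, "half_up", 0.66),
        (3, 1796, "half_up", 0.17),
        (314, 44688, "half_up", 0.70),
        (73, 24406, "half_up", 0.30),
        (0, 1234, "half_up", 0.0),
    ])
    def test_percentages(self, count, total, mode, expected):
        assert proportion_of_reports(count, total, mode) == pytest.approx(expected)

    def test_zero_denominator_is_na(self):
        assert proportion_of_reports(5, 0) is None


class TestBuildContingency:
    def test_matches_enumeration_on_random_collections(self):
        rng = random.Random(7)
        pts_pool = ["Colitis", "Crohn's disease", "Headache", "Nausea", "Proctitis"]
        drug_pool = [("COSENTYX", "PS"), ("TALTZ", "PS"), ("COSENTYX", "C"),
                     ("ASPIRIN", "PS")]
        for trial in range(25):
            reports = [
                make_report(
                    f"C{i}",
                    pts=tuple(rng.sample(pts_pool, rng.randint(1, 4))),
                    drugs=tuple(rng.sample(drug_pool, rng.randint(1, 2))),
                )
                for i in range(rng.randint(1, 200))
            ]
            target = set(rng.sample(pts_pool, rng.randint(1, 3)))
            got = build_contingency(reports, "secukinumab", IL17_DICTIONARY, target)
            assert (got.a, got.b, got.c, got.d) == brute_force_contingency(
                reports, "secukinumab", IL17_DICTIONARY, target
            )

    def test_cells_sum_to_total_event_tally(self):
        reports = [
            make_report("C1", pts=("Colitis", "Colitis", "Headache")),  # dup PT once
            make_report("C2", pts=("Crohn's disease",), drugs=(("TALTZ", "PS"),)),
        ]
        t = build_contingency(reports, "secukinumab", IL17_DICTIONARY, {"Colitis"})
        assert t.total == 3  # distinct PTs only: 2 + 1

    def test_no_exposed_reports_gives_empty_exposure_row(self):
        reports = [make_report("C1", drugs=(("ASPIRIN", "PS"),))]
        t = build_contingency(reports, "secukinumab", IL17_DICTIONARY, {"Colitis"})
        assert (t.a, t.b) == (0, 0)

    def test_empty_pt_set_is_config_error(self):
        with pytest.raises(ConfigError, match="empty PT set"):
            build_contingency([], "secukinumab", IL17_DICTIONARY, set())

    def test_pt_matching_is_exact_after_casefold(self):
        reports = [make_report("C1", pts=("  colitis ULCERATIVE ",))]
        t = build_contingency(reports, "secukinumab", IL17_DICTIONARY,
                              {"Colitis ulcerative"})
        assert t.a == 1
        t2 = build_contingency(reports, "secukinumab", IL17_DICTIONARY, {"Colitis"})
        assert t2.a == 0  # "Colitis ulcerative" is not "Colitis"


@pytest.fixture(scope="module")
def planted_run():
    cfg = study_config(
        n_reports=8000,
        planted=(PlantedAssociation("secukinumab", "Inflammatory bowel disease", 8.0),),
        seed=11,
    )
    reports = deduplicate(generate_reports(cfg))
    return run_disproportionality(reports, IL17_DICTIONARY, DEFAULT_GROUPS)


class TestRunDisproportionality:
    def test_group_totals_equal_sum_of_per_pt_counts(self, planted_run):
        for (drug, group), sub in planted_run.groupby(["drug", "group"]):
            total = sub.loc[sub.pt == "Total events of interest", "count"].item()
            per_pt = sub.loc[sub.pt != "Total events of interest", "count"].sum()
            assert total == per_pt

    def test_only_planted_pair_is_flagged_among_totals(self, planted_run):
        totals = planted_run[planted_run.pt == "Total events of interest"]
        flagged = totals[totals.signal]
        assert [(r.drug, r.group) for r in flagged.itertuples()] == [
            ("secukinumab", "IBD")
        ]

    def test_table_shape(self, planted_run):
        # one row per drug x PT plus one total row per drug x group
        n_drugs = len(IL17_DICTIONARY.actives)
        expected = sum(n_drugs * (len(g.pts) + 1) for g in DEFAULT_GROUPS)
        assert len(planted_run) == expected
        assert list(planted_run.columns) == [
            "drug", "group", "pt", "count", "ror", "ci_low", "ci_high", "signal"
        ]

    def test_duplicate_group_names_rejected(self):
        groups = (EventGroup("X", ("Colitis",)), EventGroup("X", ("Proctitis",)))
        with pytest.raises(ConfigError, match="unique"):
            run_disproportionality([], IL17_DICTIONARY, groups)
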