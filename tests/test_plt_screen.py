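"""Hit parsing, PLT categories, Fisher's exact test, and 2^-ddCt."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from converge.plt_screen import (
    CategoryThresholds,
    HitRecord,
    ScreenError,
    benjamini_hochberg,
    categorize,
    categorize_all,
    fisher_exact_2x2,
    fold_change_ddct,
    parse_hits,
    read_taxon_map,
)

TAXON_MAP = {"plant_": "plant", "insect_": "insect"}


def hit_row(q, s, ident, evalue):
    return f"{q}\t{s}\t{ident}\t100\t5\t0\t1\t100\t1\t100\t{evalue}\t180.0"


class TestParseHits:
    def test_evalue_cutoff_drops_weak_hits(self):
        text = "\n".join(
            [hit_row("q1", "plant_x", 90.0, "1e-50"), hit_row("q1", "insect_y", 80.0, "0.01")]
        )
        table = parse_hits(io.StringIO(text), TAXON_MAP)
        assert len(table.records) == 1
        assert table.n_dropped_evalue == 1
        assert table.records[0].group == "plant"

    def test_boundary_evalue_retained(self):
        table = parse_hits(io.StringIO(hit_row("q", "plant_x", 90.0, "1e-3")), TAXON_MAP)
        assert len(table.records) == 1

    def test_empty_file(self):
        assert parse_hits(io.StringIO(""), TAXON_MAP).records == []

    def test_generated_rows_counted(self):
        rng = np.random.default_rng(0)
        rows, above = [], 0
        for i in range(100):
            weak = rng.random() < 0.4
            above += weak
            rows.append(
                hit_row(f"q{i}", "plant_x", 50.0, "0.5" if weak else "1e-20")
            )
        table = parse_hits(io.StringIO("\n".join(rows)), TAXON_MAP)
        assert len(table.records) == 100 - above
        assert table.n_dropped_evalue == above

    def test_unknown_subject_grouped_other_with_count(self):
        table = parse_hits(io.StringIO(hit_row("q", "mystery", 50.0, "1e-9")), TAXON_MAP)
        assert table.records[0].group == "other"
        assert table.n_unknown_subject == 1

    def test_malformed_row_reports_line(self):
        text = hit_row("q1", "plant_x", 90.0, "1e-9") + "\nq2\tplant_y\tnot_a_number\t" + "\t".join(["1"] * 9)
        with pytest.raises(ScreenError, match="line 2"):
            parse_hits(io.StringIO(text), TAXON_MAP)

    def test_identity_range_validated(self):
        with pytest.raises(ScreenError, match=r"\[0, 100\]"):
            parse_hits(io.StringIO(hit_row("q", "plant_x", 105.0, "1e-9")), TAXON_MAP)

    def test_taxon_map_round_trip(self):
        m = read_taxon_map(io.StringIO("plant_\tplant\ninsect_\tINSECT\n"))
        assert m == {"plant_": "plant", "insect_": "insect"}


def make_hits(query, plant=None, insect=None):
    hits = []
    if plant is not None:
        hits.append(HitRecord(query, "plant_x", plant, 100, 1e-20, 100.0, "plant"))
    if insect is not None:
        hits.append(HitRecord(query, "insect_x", insect, 100, 1e-20, 100.0, "insect"))
    return hits


class TestCategorize:
    @pytest.mark.parametrize(
        "plant,insect,expected",
        [
            (96.0, 88.0, "i"),      # conserved: near-identical to both
            (92.0, 45.0, "ii"),     # high plant, low insect
            (90.0, None, "iii"),    # plant-only
            (None, 90.0, "not_plt"),
            (80.0, 90.0, "not_plt"),  # insect beats plant
            (92.0, 92.0, "not_plt"),  # tie is conservative
        ],
    )
    def test_category_boundaries(self, plant, insect, expected):
        call = categorize("q", make_hits("q", plant, insect))
        assert call.category == expected

    def test_configurable_thresholds(self):
        th = CategoryThresholds(plant_mid=50.0)
        call = categorize("q", make_hits("q", 60.0, 20.0), thresholds=th)
        assert call.category == "ii"

    @settings(derandomize=True, max_examples=50)
    @given(
        plant=st.one_of(st.none(), st.floats(0, 100)),
        insect=st.one_of(st.none(), st.floats(0, 100)),
    )
    def test_every_query_gets_exactly_one_label(self, plant, insect):
        call = categorize("q", make_hits("q", plant, insect))
        assert call.category in {"i", "ii", "iii", "not_plt"}

    def test_counts_partition_queries(self):
        from converge.plt_screen import HitTable

        records = (
            make_hits("q1", 96.0, 88.0)
            + make_hits("q2", 92.0, 45.0)
            + make_hits("q3", 90.0, None)
            + make_hits("q4", None, 70.0)
        )
        calls = categorize_all(HitTable(records))
        assert len(calls) == 4
        assert sorted(c.category for c in calls) == ["i", "ii", "iii", "not_plt"]


def enumerate_fisher(a, b, c, d):
    """Exact two-sided p by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs_num = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num <= obs_num:
            total += num
    return total / denom


class TestFisher:
    def test_proportional_rows_give_one(self):
        assert fisher_exact_2x2(2, 3, 4, 6) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_separation_closed_form(self):
        # [[5,0],[0,5]]: only two extreme tables -> p = 2 / C(10,5)
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b + c + d == 0:
                continue
            p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(enumerate_fisher(int(a), int(b), int(c), int(d)), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            _, p_ref = scipy_fisher([[a, b], [c, d]])
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(p_ref, rel=1e-7, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
    def test_symmetry_under_transposition_and_swaps(self, table):
        a, b, c, d = table
        p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_exact_2x2(a, c, b, d), abs=1e-12)  # transpose
        assert p == pytest.approx(fisher_exact_2x2(c, d, a, b), abs=1e-12)  # row swap
        assert p == pytest.approx(fisher_exact_2x2(b, a, d, c), abs=1e-12)  # col swap

    def test_all_zero_rejected(self):
        with pytest.raises(ScreenError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestFoldChange:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((21.0, 21.0, 21.0, 21.0), 1.0),
            ((20.0, 18.0, 21.0, 18.0), 2.0),   # ddCt = -1
            ((25.0, 18.0, 22.0, 18.0), 0.125),  # ddCt = 3
        ],
    )
    def test_reference_points(self, cts, expected):
        assert fold_change_ddct(*cts) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(5, 40), st.floats(5, 40))
    def test_test_equal_to_calibrator_is_unity(self, ct_t, ct_r):
        assert fold_change_ddct(ct_t, ct_r, ct_t, ct_r) == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ScreenError):
            fold_change_ddct(float("nan"), 1.0, 1.0, 1.0)


def test_benjamini_hochberg_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.8, 0.04]
    q = benjamini_hochberg(p)
    assert np.all(q >= p)
    assert np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
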