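import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsmine.composition import (
    CompositionVector,
    chi2_sf,
    chi2_sf_df1,
    compare_groups,
    composition,
    kruskal_wallis,
)
from pbsmine.records import STANDARD_RESIDUES, ProteinRecord

from oracles import kruskal_wallis_oracle


def _protein(seq, pid="p"):
    return ProteinRecord(pid, "test", seq)


# --- composition -----------------------------------------------------------


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("AAAA", {"A": 100.0}),
        ("ACACAC", {"A": 50.0, "C": 50.0}),
        ("AAXA", {"A": 100.0}),  # X excluded from numerator and denominator
    ],
)
def test_composition_worked_examples(sequence, expected):
    vector = composition(_protein(sequence))
    for residue in STANDARD_RESIDUES:
        assert vector.percent[residue] == pytest.approx(expected.get(residue, 0.0))


def test_composition_all_x_rejected():
    with pytest.raises(ValueError):
        composition(_protein("XXX"))


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=200))
@settings(derandomize=True, max_examples=100)
def test_composition_sums_to_100(sequence):
    if set(sequence) == {"X"}:
        return
    vector = composition(_protein(sequence))
    assert sum(vector.percent.values()) == pytest.approx(100.0, abs=1e-9)


# --- Kruskal–Wallis --------------------------------------------------------


def test_kruskal_wallis_worked_example():
    # mean ranks 2 and 5: H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2)
    result = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert result.H == pytest.approx(3.857142857, abs=1e-9)
    assert result.H_corrected == pytest.approx(result.H)
    assert result.df == 1
    assert result.p == pytest.approx(0.0495, abs=5e-4)


def test_kruskal_wallis_identical_groups():
    result = kruskal_wallis([[1, 2], [1, 2]])
    assert result.H_corrected == pytest.approx(0.0, abs=1e-12)
    assert result.p == pytest.approx(1.0)


def test_kruskal_wallis_all_values_identical_warns():
    with pytest.warns(UserWarning):
        result = kruskal_wallis([[5, 5], [5, 5]])
    assert result.p == 1.0


def test_kruskal_wallis_rank_invariance_under_monotone_transform():
    groups = [[0.1, 0.7, 2.0], [0.3, 1.5], [0.2, 2.5, 3.0]]
    transformed = [[np.exp(v) for v in g] for g in groups]
    assert kruskal_wallis(groups).H == pytest.approx(
        kruskal_wallis(transformed).H
    )


def test_kruskal_wallis_input_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1], []])
    with pytest.raises(ValueError):
        kruskal_wallis([[1], [2]])


def test_kruskal_wallis_matches_bruteforce_and_scipy_on_random_instances():
    rng = np.random.default_rng(1)
    for case in range(200):
        k = int(rng.integers(2, 5))
        groups = [
            # integer draws force ties regularly
            list(rng.integers(0, 8, size=int(rng.integers(2, 10))).astype(float))
            for _ in range(k)
        ]
        pooled = [v for g in groups for v in g]
        if len(set(pooled)) == 1:
            continue  # degenerate case covered by its own test
        result = kruskal_wallis(groups)
        h_oracle, h_corrected_oracle = kruskal_wallis_oracle(groups)
        assert result.H == pytest.approx(h_oracle, abs=1e-10), f"case {case}"
        assert result.H_corrected == pytest.approx(h_corrected_oracle, abs=1e-10)
        expected = scipy.stats.kruskal(*groups)
        assert result.H_corrected == pytest.approx(expected.statistic, abs=1e-10)
        assert result.p == pytest.approx(expected.pvalue, abs=1e-10)


def test_tie_correction_never_decreases_h():
    rng = np.random.default_rng(2)
    for _ in range(50):
        groups = [
            list(rng.integers(0, 4, size=6).astype(float)) for _ in range(2)
        ]
        if len(set(sum(groups, []))) == 1:
            continue
        result = kruskal_wallis(groups)
        assert result.H_corrected >= result.H - 1e-12


def test_chi2_tail_agrees_with_df1_closed_form():
    for x in (0.1, 1.0, 3.84, 6.63, 15.0):
        assert chi2_sf(x, 1) == pytest.approx(chi2_sf_df1(x), rel=1e-12)


def test_null_type_one_error_rate_calibrated():
    """Flag rate at alpha 0.05 under the null is 0.05 +- 0.02 (2000 tests)."""
    rng = np.random.default_rng(42)
    rejections = 0
    n_tests = 2000
    for _ in range(n_tests):
        a = list(rng.normal(size=10))
        b = list(rng.normal(size=10))
        if kruskal_wallis([a, b]).p <= 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_tests <= 0.07


# --- group comparison ------------------------------------------------------


def _vectors(values_by_residue, n, prefix):
    vectors = []
    for i in range(n):
        percent = {r: 0.0 for r in STANDARD_RESIDUES}
        for residue, values in values_by_residue.items():
            percent[residue] = values[i]
        remainder = 100.0 - sum(percent.values())
        percent["G"] += remainder
        vectors.append(CompositionVector(f"{prefix}{i}", percent))
    return vectors


def test_planted_glutamate_shift_flagged():
    thermo = _vectors({"E": [3.6, 3.7, 3.8, 3.7, 3.6, 3.9]}, 6, "t")
    meso = _vectors({"E": [2.4, 2.5]}, 2, "m")
    table = compare_groups("apcA", thermo, meso)
    row = table[table["residue"] == "E"].iloc[0]
    assert row["sig_0.05"]
    assert "±" in row["thermophile"]


def test_identical_groups_yield_no_flags():
    thermo = _vectors({"E": [3.0, 3.0, 3.0]}, 3, "t")
    meso = _vectors({"E": [3.0, 3.0, 3.0]}, 3, "m")
    with pytest.warns(UserWarning):
        table = compare_groups("apcA", thermo, meso)
    assert not table["sig_0.05"].any()
    assert not table["sig_0.01"].any()


def test_small_group_skipped_with_warning(caplog):
    import logging

    thermo = _vectors({"E": [3.0, 3.1]}, 2, "t")
    meso = _vectors({"E": [2.0]}, 1, "m")
    with caplog.at_level(logging.WARNING):
        table = compare_groups("apcA", thermo, meso)
    assert table.empty
    assert any("skipped" in r.message for r in caplog.records)


def test_compare_groups_sorted_by_p():
    rng = np.random.default_rng(3)
    thermo = _vectors({"E": list(3 + rng.normal(0, 0.1, 5)),
                       "K": list(2 + rng.normal(0, 0.1, 5))}, 5, "t")
    meso = _vectors({"E": list(2 + rng.normal(0, 0.1, 4)),
                     "K": list(2 + rng.normal(0, 0.1, 4))}, 4, "m")
    table = compare_groups("cpcB", thermo, meso)
    assert list(table["p"]) == sorted(table["p"])
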