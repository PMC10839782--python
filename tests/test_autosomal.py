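"""Forensic-parameter suite, combined powers and the HWE exact test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strpopgen import (
    GenotypeTable,
    MarkerDef,
    allele_frequencies,
    bonferroni,
    combined_powers,
    expected_heterozygosity,
    forensic_params,
    hwe_exact_test,
    match_probability,
    observed_heterozygosity,
    pic,
    power_of_discrimination,
    power_of_exclusion,
    typical_paternity_index,
)
from strpopgen.simulate import simulate_autosomal_genotypes


def _table(genotypes, marker="M"):
    panel = {marker: MarkerDef(marker, "autosomal", 4)}
    samples = [f"s{i}" for i in range(len(genotypes))]
    return GenotypeTable.from_calls(
        panel, samples, {}, {marker: dict(zip(samples, genotypes))}
    )


def test_direct_counting_frequencies():
    t = _table([("9", "9"), ("9", "10")])
    fmap, g = allele_frequencies(t, "M")
    assert g == 4
    assert fmap == {"9": 0.75, "10": 0.25}
    mono = _table([("9", "9"), ("9", "9")])
    assert allele_frequencies(mono, "M")[0] == {"9": 1.0}
    with pytest.raises(KeyError):
        allele_frequencies(t, "NOPE")


def test_frequencies_converge_to_truth(rng):
    truth = {"8": 0.55, "9": 0.3, "10": 0.15}
    genos = simulate_autosomal_genotypes(truth, 20_000, seed=rng)
    t = _table(genos)
    fmap, _ = allele_frequencies(t, "M")
    for a, p in truth.items():
        assert fmap[a] == pytest.approx(p, abs=0.01)


def test_observed_heterozygosity():
    het = _table([("9", "10"), ("9", "11")])
    assert observed_heterozygosity(het, "M") == 1.0
    hom = _table([("9", "9"), ("10", "10")])
    assert observed_heterozygosity(hom, "M") == 0.0
    mix = _table([("9", "10")] * 3 + [("9", "9")] * 2)
    assert observed_heterozygosity(mix, "M") == pytest.approx(0.6)


def test_expected_heterozygosity_closed_forms():
    assert expected_heterozygosity({"9": 1.0}, 100) == 0.0
    assert expected_heterozygosity({"9": 0.5, "10": 0.5}, 100) == pytest.approx(
        100 / 99 * 0.5
    )
    with pytest.raises(ValueError):
        expected_heterozygosity({"9": 1.0}, 1)


def test_pic_closed_forms_and_oracle(rng):
    assert pic({"9": 1.0}) == 0.0
    assert pic({"9": 0.5, "10": 0.5}) == pytest.approx(0.375)
    for _ in range(25):
        p = rng.dirichlet(np.full(10, 0.8))
        brute = 1.0 - sum(x * x for x in p) - sum(
            2 * p[i] ** 2 * p[j] ** 2
            for i in range(len(p))
            for j in range(i + 1, len(p))
        )
        assert pic(p) == pytest.approx(brute, abs=1e-12)


def test_h_exp_matches_brute_force_pairs(rng):
    """Nei estimator equals g/(g-1) * sum over ordered distinct pairs."""
    for _ in range(10):
        p = rng.dirichlet(np.full(6, 1.0))
        g = 200
        brute = g / (g - 1) * sum(
            p[i] * p[j] for i in range(6) for j in range(6) if i != j
        )
        assert expected_heterozygosity(p, g) == pytest.approx(brute, abs=1e-12)


def test_match_probability_and_pd():
    distinct = _table([("9", "10"), ("9", "11"), ("10", "11"), ("9", "9")])
    assert match_probability(distinct, "M") == pytest.approx(0.25)
    shared = _table([("9", "10"), ("10", "9")])  # same unordered genotype
    assert match_probability(shared, "M") == 1.0
    assert power_of_discrimination(shared, "M") == 0.0
    # PM printed for the least-discriminating locus maps exactly to its PD
    assert 1.0 - 0.221084 == pytest.approx(0.778916, abs=1e-12)


def test_power_of_exclusion_printed_anchors():
    assert power_of_exclusion(0.61306) == pytest.approx(0.306843, abs=1e-4)
    assert power_of_exclusion(0.94586) == pytest.approx(0.889690, abs=1e-4)
    assert power_of_exclusion(0.0) == 0.0
    with pytest.raises(ValueError):
        power_of_exclusion(1.2)


def test_typical_paternity_index_printed_anchors():
    assert typical_paternity_index(0.61306) == pytest.approx(1.292181, abs=1e-4)
    assert typical_paternity_index(0.94586) == pytest.approx(9.235294, abs=1e-3)
    assert typical_paternity_index(0.5) == 1.0
    with pytest.raises(ValueError):
        typical_paternity_index(1.0)


@settings(max_examples=100, derandomize=True)
@given(st.floats(0.0, 0.999), st.floats(0.0, 0.999))
def test_pe_tpi_monotone_in_h_obs(h1, h2):
    lo, hi = sorted((h1, h2))
    assert power_of_exclusion(lo) <= power_of_exclusion(hi) + 1e-15
    assert typical_paternity_index(lo) <= typical_paternity_index(hi) + 1e-15


def test_pd_pm_complement_exact(sim_table):
    table, _ = sim_table
    for marker in table.markers("autosomal")[:10]:
        pm = match_probability(table, marker, "length")
        assert power_of_discrimination(table, marker, "length") == 1.0 - pm


def test_combined_powers():
    one = pd.DataFrame({"pe": [0.3], "pd": [0.9]})
    cp1 = combined_powers(one)
    assert cp1.cpd == pytest.approx(0.9) and cp1.cpe == pytest.approx(0.3)
    two = pd.DataFrame({"pe": [0.5, 0.5], "pd": [0.9, 0.9]})
    assert combined_powers(two).cpd == pytest.approx(0.99)
    with pytest.raises(ValueError):
        combined_powers(pd.DataFrame({"pe": [], "pd": []}))


def test_combined_powers_log_space_oracle(rng):
    """Log-space residual equals an exact rational product over 52 loci."""
    pd_vals = rng.uniform(0.8, 0.999, size=52)
    pe_vals = rng.uniform(0.3, 0.9, size=52)
    df = pd.DataFrame({"pe": pe_vals, "pd": pd_vals})
    cp = combined_powers(df)
    exact_pd = math.prod(Fraction(1) - Fraction(x) for x in pd_vals)
    exact_pe = math.prod(Fraction(1) - Fraction(x) for x in pe_vals)
    assert cp.residual_cpd == pytest.approx(float(exact_pd), rel=1e-10)
    assert cp.residual_cpe == pytest.approx(float(exact_pe), rel=1e-10)
    assert "E-" in cp.cpd_repr and cp.cpd_repr.startswith("1-")


def test_forensic_params_frame(sim_table):
    table, _ = sim_table
    df = forensic_params(table, "length")
    assert len(df) == 52
    for col in ("h_obs", "h_exp", "pic", "pm", "pd", "pe"):
        assert df[col].between(0, 1).all()
    assert np.allclose(df["pd"], 1.0 - df["pm"])
    assert np.allclose(df["tpi"], 1.0 / (2.0 * (1.0 - df["h_obs"])))


# -- HWE ------------------------------------------------------------------


def test_hwe_enumeration_matches_exhaustive_oracle():
    """p for (AA=1, AB=2, BB=1): every array is as or less probable."""
    res = hwe_exact_test({("A", "A"): 1, ("A", "B"): 2, ("B", "B"): 1})
    assert res.method == "enumeration"
    assert res.p_value == pytest.approx(1.0)
    # exhaustive oracle over heterozygote counts 0, 2, 4 with margins (4, 4):
    # conditional probs 6/70, 48/70, 16/70 -> observed 48/70 is the mode
    assert res.p_value == pytest.approx((6 + 48 + 16) / 70)


def test_hwe_enumeration_two_allele_tail():
    # all homozygotes, p = q: the most extreme array
    res = hwe_exact_test({("A", "A"): 50, ("B", "B"): 50})
    assert res.p_value < 1e-6


def test_hwe_monomorphic_convention():
    assert hwe_exact_test({("A", "A"): 30}).p_value == 1.0


def test_hwe_monte_carlo_detects_excess():
    counts = {("A", "A"): 40, ("B", "B"): 40, ("C", "C"): 40}
    res = hwe_exact_test(counts, n_permutations=2000, seed=1)
    assert res.method == "monte-carlo"
    assert res.p_value < 0.01


def test_hwe_monte_carlo_seed_reproducible():
    counts = {
        ("A", "A"): 10, ("A", "B"): 22, ("B", "B"): 11,
        ("A", "C"): 9, ("B", "C"): 12, ("C", "C"): 6,
    }
    r1 = hwe_exact_test(counts, 4000, seed=42)
    r2 = hwe_exact_test(counts, 4000, seed=42)
    assert r1.p_value == r2.p_value
    assert 0.0 < r1.p_value <= 1.0


def test_hwe_power_increases_with_inbreeding(rng):
    """Rejections at alpha=0.05 are more frequent under F=0.3 than F=0."""
    freqs = dict(zip("abcd", rng.dirichlet(np.full(4, 2.0))))
    hits = {0.0: 0, 0.3: 0}
    for f in hits:
        for i in range(40):
            genos = simulate_autosomal_genotypes(freqs, 150, F=f, seed=1000 + i)
            counts: dict = {}
            for a, b in genos:
                key = tuple(sorted((a, b)))
                counts[key] = counts.get(key, 0) + 1
            p = hwe_exact_test(counts, 600, seed=i).p_value
            hits[f] += p < 0.05
    assert hits[0.3] > hits[0.0]
    assert hits[0.3] >= 35  # strong departure is essentially always caught


def test_bonferroni():
    thr, flags = bonferroni({f"m{i}": 0.5 for i in range(52)}, 0.05)
    assert thr == pytest.approx(0.05 / 52)
    thr1, _ = bonferroni({"a": 0.2}, 0.05)
    assert thr1 == 0.05
    _, f2 = bonferroni({"a": 0.01} | {f"m{i}": 0.5 for i in range(51)}, 0.05)
    assert not f2["a"]  # 0.01 > 0.05/52: not flagged after correction
    with pytest.raises(ValueError):
        bonferroni({}, 0.05)
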