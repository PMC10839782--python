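"""Fst/Rst estimators and distance-matrix behavior."""

import numpy as np
import pytest

from strpopgen import (
    DistanceMatrix,
    GenotypeTable,
    MarkerDef,
    nearest_populations,
    pairwise_fst,
    pairwise_rst,
    simulate_diverged_populations,
    slatkin_rst,
    weir_cockerham_theta,
)


def _diploid_table(calls, name="pop"):
    markers = sorted(calls)
    panel = {m: MarkerDef(m, "autosomal", 4) for m in markers}
    samples = sorted({s for c in calls.values() for s in c})
    return GenotypeTable.from_calls(panel, samples, {}, calls, {})


def _haploid_table(calls):
    panel = {m: MarkerDef(m, "y_single", 4) for m in calls}
    samples = sorted({s for c in calls.values() for s in c})
    sex = {s: "M" for s in samples}
    return GenotypeTable.from_calls(panel, samples, sex, {}, calls)


@pytest.fixture(scope="module")
def diverged_pops(rng):
    anc = {
        f"L{i}": dict(zip(["8", "9", "10", "11"], np.full(4, 0.25)))
        for i in range(10)
    }
    pops, _ = simulate_diverged_populations(anc, 0.10, 300, seed=rng)
    return pops


def test_population_vs_itself_is_zero(diverged_pops):
    t = list(diverged_pops.values())[0]
    loci = t.markers("autosomal")
    assert weir_cockerham_theta([t, t], loci) <= 1e-12
    m = pairwise_fst({"A": t, "B": t})
    assert m.get("A", "B") == 0.0  # floored; raw may be slightly negative
    assert m.raw[0, 1] <= 1e-12


def test_theta_permutation_oracle(diverged_pops, rng):
    """Randomly splitting a merged sample gives theta near zero."""
    a, b = list(diverged_pops.values())[:2]
    loci = a.markers("autosomal")
    merged = {}
    for m in loci:
        merged[m] = {**a.diploid_calls(m), **b.diploid_calls(m)}
    samples = sorted({s for c in merged.values() for s in c})
    perm = rng.permutation(len(samples))
    half = set(np.array(samples)[perm[: len(samples) // 2]])
    c1 = {m: {s: g for s, g in calls.items() if s in half} for m, calls in merged.items()}
    c2 = {m: {s: g for s, g in calls.items() if s not in half} for m, calls in merged.items()}
    theta = weir_cockerham_theta([_diploid_table(c1), _diploid_table(c2)], loci)
    assert abs(theta) < 0.01


def test_theta_invariant_under_allele_relabeling(diverged_pops):
    tables = list(diverged_pops.values())[:2]
    loci = tables[0].markers("autosomal")
    theta0 = weir_cockerham_theta(tables, loci)
    relabel = {"8": "21", "9": "33", "10": "7", "11": "15"}
    remapped = []
    for t in tables:
        calls = {
            m: {
                s: (relabel[a], relabel[b])
                for s, (a, b) in t.diploid_calls(m).items()
            }
            for m in loci
        }
        remapped.append(_diploid_table(calls))
    assert weir_cockerham_theta(remapped, loci) == pytest.approx(theta0, abs=1e-12)


def test_rst_identity_and_fixation():
    same = _haploid_table({"L": {f"s{i}": (str(10 + i % 3),) for i in range(30)}})
    assert slatkin_rst([same, same], ["L"]) <= 1e-12
    lo = _haploid_table({"L": {f"a{i}": ("10",) for i in range(20)}})
    hi = _haploid_table({"L": {f"b{i}": ("20",) for i in range(20)}})
    assert slatkin_rst([lo, hi], ["L"]) == pytest.approx(1.0)


def test_rst_affine_invariance(rng):
    counts1 = rng.integers(8, 15, 40)
    counts2 = rng.integers(10, 18, 40)

    def build(c1, c2):
        a = _haploid_table({"L": {f"a{i}": (str(int(v)),) for i, v in enumerate(c1)}})
        b = _haploid_table({"L": {f"b{i}": (str(int(v)),) for i, v in enumerate(c2)}})
        return slatkin_rst([a, b], ["L"])

    base = build(counts1, counts2)
    shifted = build(counts1 + 7, counts2 + 7)
    scaled = build(counts1 * 3, counts2 * 3)
    affine = build(counts1 * 3 + 7, counts2 * 3 + 7)
    assert shifted == pytest.approx(base, abs=1e-12)
    assert scaled == pytest.approx(base, abs=1e-12)
    assert affine == pytest.approx(base, abs=1e-12)


def test_rst_microvariant_handling():
    a = _haploid_table({"L": {f"a{i}": ("9.3" if i % 2 else "9",) for i in range(10)}})
    b = _haploid_table({"L": {f"b{i}": ("12",) for i in range(10)}})
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            slatkin_rst([a, b], ["L"], microvariants="skip")
    # floor convention: 9.3 -> 9, locus usable
    val = slatkin_rst([a, b], ["L"], microvariants="floor")
    assert val == pytest.approx(1.0)


def test_rst_excludes_multicopy_loci():
    panel = {
        "YM": MarkerDef("YM", "y_multicopy", 4),
        "YS": MarkerDef("YS", "y_single", 4),
    }

    def make(tag, ys):
        samples = [f"{tag}{i}" for i in range(10)]
        return GenotypeTable.from_calls(
            panel,
            samples,
            {s: "M" for s in samples},
            {},
            {
                "YM": {s: ("14", "17") for s in samples},
                "YS": {s: (ys,) for s in samples},
            },
        )

    with pytest.warns(UserWarning, match="YM"):
        m = pairwise_rst({"A": make("a", "10"), "B": make("b", "20")})
    assert m.get("A", "B") == pytest.approx(1.0)
    assert m.loci == ["YM", "YS"]


def test_distance_increases_with_divergence(rng):
    anc = {f"L{i}": {"9": 0.4, "10": 0.3, "11": 0.3} for i in range(12)}
    means = []
    for f_div in (0.01, 0.05, 0.15):
        thetas = []
        for rep in range(5):
            pops, _ = simulate_diverged_populations(anc, f_div, 200, seed=rng)
            thetas.append(
                weir_cockerham_theta(list(pops.values()), list(anc))
            )
        means.append(np.mean(thetas))
    assert means[0] < means[1] < means[2]


def test_nearest_populations_ranking_and_ties():
    labels = ["HAK", "AAA", "BBB", "CCC"]
    v = np.array(
        [
            [0.0, 0.02, 0.01, 0.02],
            [0.02, 0.0, 0.03, 0.04],
            [0.01, 0.03, 0.0, 0.05],
            [0.02, 0.04, 0.05, 0.0],
        ]
    )
    m = DistanceMatrix(labels, v)
    ranked = nearest_populations(m, "HAK")
    assert [r[0] for r in ranked] == ["BBB", "AAA", "CCC"]  # tie broken lexically
    assert nearest_populations(m, "HAK", k=1) == [("BBB", 0.01)]
    with pytest.raises(KeyError):
        nearest_populations(m, "NOPE")


def test_distance_matrix_invariants():
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "A"], np.zeros((2, 2)))
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0.0, -0.1], [-0.1, 0.0]]))
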