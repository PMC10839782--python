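"""Direct-counting allele frequencies and the forensic-parameter suite.

Per-locus parameters for diploid markers, as used in forensic population
reports:

* H_obs — fraction of typed individuals heterozygous at the locus.
* H_exp (= GD) — unbiased Nei gene diversity, (g/(g-1)) * (1 - sum p_i^2)
  with g the number of gene copies (2N).
* PIC — Botstein polymorphism information content.
* PM / PD — match probability (sum of squared observed genotype sample
  frequencies) and its complement, the power of discrimination.
* PE — power of exclusion in trio paternity testing, h^2 (1 - 2 h H^2)
  with h = H_obs and H = 1 - h.
* TPI — typical paternity index, 1 / (2 (1 - H_obs)).

Multi-locus combinations (CPE, CPD) are accumulated in log space so the
residuals 1 - CPE = prod(1 - PE_l) survive at magnitudes like 1e-60.  The
Hardy-Weinberg exact test conditions on allele counts: full enumeration for
two alleles, seeded Monte-Carlo permutation of the gene array otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .nomenclature import Level, allele_sort_key
from .tables import GenotypeTable

__all__ = [
    "FrequencyTable",
    "ForensicParamRow",
    "CombinedPowerResult",
    "HweResult",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "match_probability",
    "power_of_discrimination",
    "power_of_exclusion",
    "typical_paternity_index",
    "forensic_params",
    "combined_powers",
    "hwe_exact_test",
    "hwe_test_table",
    "bonferroni",
    "genotype_counts",
]


@dataclass
class FrequencyTable:
    """Per-marker allele -> relative frequency maps from direct counting.

    ``gene_counts[marker]`` is the number of gene copies counted (2N for
    diploid markers, N typed males for haploid ones); every frequency is an
    integer count divided by that gene count.
    """

    freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, fmap in self.freqs.items():
            total = math.fsum(fmap.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{marker}: frequencies sum to {total}, not 1"
                )

    @classmethod
    def from_table(
        cls,
        table: GenotypeTable,
        level: Level = "length",
        markers: Sequence[str] | None = None,
    ) -> "FrequencyTable":
        ft = cls()
        for marker in markers if markers is not None else table.markers():
            fmap, g = allele_frequencies(table, marker, level)
            ft.freqs[marker] = fmap
            ft.gene_counts[marker] = g
        return ft

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for marker, fmap in self.freqs.items():
            for allele in sorted(fmap, key=allele_sort_key):
                rows.append((marker, allele, fmap[allele], self.gene_counts[marker]))
        return pd.DataFrame(rows, columns=["marker", "allele", "frequency", "gene_count"])


def allele_frequencies(
    table: GenotypeTable, marker: str, level: Level = "length"
) -> tuple[dict[str, float], int]:
    """Direct-counting allele frequencies at one marker.

    Counts gene copies over typed samples only (complete-case per locus) and
    returns ``(allele -> count/gene_count, gene_count)``.
    """
    mdef = table.panel.get(marker)
    if mdef is None:
        raise KeyError(f"unknown marker {marker!r}")
    counts: dict[str, int] = {}
    if mdef.is_y:
        for alleles in table.haploid_calls(marker, level).values():
            for a in alleles:
                counts[a] = counts.get(a, 0) + 1
    else:
        for pair in table.diploid_calls(marker, level).values():
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
    g = sum(counts.values())
    if g == 0:
        raise ValueError(f"no typed samples at marker {marker!r}")
    return {a: c / g for a, c in counts.items()}, g


def genotype_counts(
    table: GenotypeTable, marker: str, level: Level = "length"
) -> dict[tuple[str, str], int]:
    """Unordered-genotype counts at a diploid marker."""
    counts: dict[tuple[str, str], int] = {}
    for a1, a2 in table.diploid_calls(marker, level).values():
        key = tuple(sorted((a1, a2), key=allele_sort_key))
        counts[key] = counts.get(key, 0) + 1  # type: ignore[index]
    return counts


def observed_heterozygosity(
    table: GenotypeTable, marker: str, level: Level = "length"
) -> float:
    """Fraction of typed samples carrying two distinct alleles."""
    calls = table.diploid_calls(marker, level)
    if not calls:
        raise ValueError(f"no typed samples at marker {marker!r}")
    het = sum(1 for a1, a2 in calls.values() if a1 != a2)
    return het / len(calls)


def expected_heterozygosity(freqs: Mapping[str, float] | Sequence[float], gene_count: int) -> float:
    """Unbiased Nei gene diversity (g/(g-1)) (1 - sum p^2)."""
    if gene_count < 2:
        raise ValueError("gene_count must be >= 2")
    p = _as_probs(freqs)
    return gene_count / (gene_count - 1) * (1.0 - float(np.sum(p * p)))


def pic(freqs: Mapping[str, float] | Sequence[float]) -> float:
    """Botstein polymorphism information content."""
    p = _as_probs(freqs)
    sum_p2 = float(np.sum(p * p))
    sum_p4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - sum_p2 - (sum_p2 * sum_p2 - sum_p4)


def match_probability(
    table: GenotypeTable, marker: str, level: Level = "length"
) -> float:
    """PM: sum of squared observed genotype sample frequencies."""
    counts = genotype_counts(table, marker, level)
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"no typed samples at marker {marker!r}")
    return math.fsum((c / n) ** 2 for c in counts.values())


def power_of_discrimination(
    table: GenotypeTable, marker: str, level: Level = "length"
) -> float:
    """PD = 1 - PM, exactly."""
    return 1.0 - match_probability(table, marker, level)


def power_of_exclusion(h_obs: float) -> float:
    """Trio paternity power of exclusion, h^2 (1 - 2 h H^2), H = 1 - h."""
    if not 0.0 <= h_obs <= 1.0:
        raise ValueError(f"H_obs {h_obs} outside [0, 1]")
    h = h_obs
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def typical_paternity_index(h_obs: float) -> float:
    """TPI = 1 / (2 (1 - H_obs)); undefined at H_obs = 1."""
    if not 0.0 <= h_obs <= 1.0:
        raise ValueError(f"H_obs {h_obs} outside [0, 1]")
    if h_obs == 1.0:
        raise ValueError("TPI undefined when all samples are heterozygous")
    return 1.0 / (2.0 * (1.0 - h_obs))


@dataclass(frozen=True)
class ForensicParamRow:
    marker: str
    level: Level
    n_samples: int
    h_obs: float
    h_exp: float
    pic: float
    pm: float
    pd: float
    pe: float
    tpi: float

    @property
    def gd(self) -> float:
        """Gene diversity; the same number as H_exp by construction."""
        return self.h_exp


def forensic_params(
    table: GenotypeTable,
    level: Level = "length",
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-locus forensic parameters for the autosomal markers of a table."""
    if markers is None:
        markers = table.markers("autosomal")
    rows = []
    for marker in markers:
        fmap, g = allele_frequencies(table, marker, level)
        h_obs = observed_heterozygosity(table, marker, level)
        pm = match_probability(table, marker, level)
        rows.append(
            ForensicParamRow(
                marker=marker,
                level=level,
                n_samples=g // 2,
                h_obs=h_obs,
                h_exp=expected_heterozygosity(fmap, g),
                pic=pic(fmap),
                pm=pm,
                pd=1.0 - pm,
                pe=power_of_exclusion(h_obs),
                tpi=typical_paternity_index(h_obs) if h_obs < 1.0 else float("inf"),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class CombinedPowerResult:
    """Multi-locus combined exclusion/discrimination power.

    The residuals 1 - CPE and 1 - CPD are kept in full precision (computed
    as exp of summed log1p terms) and formatted in the conventional
    ``1-5.0779620E-21`` style.
    """

    cpe: float
    cpd: float
    residual_cpe: float
    residual_cpd: float
    n_loci: int

    @staticmethod
    def _fmt(residual: float) -> str:
        return f"1-{residual:.7E}"

    @property
    def cpe_repr(self) -> str:
        return self._fmt(self.residual_cpe)

    @property
    def cpd_repr(self) -> str:
        return self._fmt(self.residual_cpd)


def combined_powers(params: pd.DataFrame) -> CombinedPowerResult:
    """CPE = 1 - prod(1 - PE_l), CPD = 1 - prod(1 - PD_l), in log space."""
    if len(params) == 0:
        raise ValueError("need at least one locus")

    def residual(values) -> float:
        if any(x >= 1.0 for x in values):
            return 0.0  # a fully informative locus saturates the combination
        return math.exp(math.fsum(math.log1p(-x) for x in values))

    res_pe = residual(params["pe"])
    res_pd = residual(params["pd"])
    return CombinedPowerResult(
        cpe=1.0 - res_pe,
        cpd=1.0 - res_pd,
        residual_cpe=res_pe,
        residual_cpd=res_pd,
        n_loci=len(params),
    )


# -- Hardy-Weinberg exact test -------------------------------------------


@dataclass(frozen=True)
class HweResult:
    marker: str
    p_value: float
    method: str  # "enumeration" | "monte-carlo"
    n_permutations: int
    seed: int | None
    n_typed: int


def _log_array_prob(counts: np.ndarray, het: int) -> float:
    """Log of the margin-free part of the conditional genotype-array
    probability given allele counts: H log 2 - sum log n_g!."""
    return het * math.log(2.0) - float(np.sum(gammaln(counts + 1.0)))


def hwe_exact_test(
    counts: Mapping[tuple[str, str], int],
    n_permutations: int = 17000,
    seed: int | None = None,
    marker: str = "",
) -> HweResult:
    """Exact test of Hardy-Weinberg proportions conditioned on allele counts.

    The p-value is the probability, under the exact conditional distribution
    of genotype arrays given the observed allele counts, of arrays whose
    conditional probability is at most that of the observed array.  With two
    alleles the distribution is enumerated in full; with more, gene copies
    are permuted Monte-Carlo style (add-one estimator, so the result is a
    valid p-value), with the replicate count and seed recorded.
    """
    if not counts:
        raise ValueError("empty genotype counts")
    alleles = sorted({a for pair in counts for a in pair})
    n = sum(counts.values())
    if n < 1:
        raise ValueError("no typed samples")
    if len(alleles) == 1:
        return HweResult(marker, 1.0, "enumeration", 0, seed, n)
    if len(alleles) == 2:
        p = _hwe_two_allele(counts, alleles)
        return HweResult(marker, p, "enumeration", 0, seed, n)
    p = _hwe_monte_carlo(counts, alleles, n_permutations, seed)
    return HweResult(marker, p, "monte-carlo", n_permutations, seed, n)


def _hwe_two_allele(counts: Mapping[tuple[str, str], int], alleles: list[str]) -> float:
    a, b = alleles
    n_ab_obs = counts.get((a, b), 0) + counts.get((b, a), 0)
    n_aa = counts.get((a, a), 0)
    n_bb = counts.get((b, b), 0)
    n = n_aa + n_ab_obs + n_bb
    n_a = 2 * n_aa + n_ab_obs
    # enumerate all heterozygote counts with the same margins and parity
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    logp = np.empty_like(hets, dtype=float)
    for i, h in enumerate(hets):
        gaa = (n_a - h) // 2
        gbb = n - gaa - h
        arr = np.array([gaa, h, gbb], dtype=float)
        logp[i] = _log_array_prob(arr, int(h))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[list(hets).index(n_ab_obs)]
    return float(probs[probs <= obs * (1.0 + 1e-12)].sum())


def _hwe_monte_carlo(
    counts: Mapping[tuple[str, str], int],
    alleles: list[str],
    n_permutations: int,
    seed: int | None,
) -> float:
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    n = sum(counts.values())
    genes = np.empty(2 * n, dtype=np.int64)
    obs_counts = np.zeros(k * k, dtype=np.int64)
    pos = 0
    het_obs = 0
    for (a, b), c in counts.items():
        i, j = sorted((idx[a], idx[b]))
        obs_counts[i * k + j] += c
        if i != j:
            het_obs += c
        genes[pos : pos + c] = i
        genes[pos + c : pos + 2 * c] = j
        pos += 2 * c
    t_obs = _log_array_prob(obs_counts[obs_counts > 0].astype(float), het_obs)

    rng = np.random.default_rng(seed)
    hits = 0
    remaining = n_permutations
    # batched shuffles (argsort of random keys row-wise), chunked for memory
    while remaining > 0:
        B = min(remaining, 2000)
        remaining -= B
        keys = rng.random((B, 2 * n), dtype=np.float32)
        order = np.argsort(keys, axis=1)
        shuffled = genes[order]  # (B, 2n)
        g1 = shuffled[:, 0::2]
        g2 = shuffled[:, 1::2]
        lo = np.minimum(g1, g2)
        hi = np.maximum(g1, g2)
        codes = lo * k + hi  # (B, n)
        het = (lo != hi).sum(axis=1)
        offset = (np.arange(B)[:, None] * (k * k)).astype(np.int64)
        flat = (codes + offset).ravel()
        tab = np.bincount(flat, minlength=B * k * k).reshape(B, k * k)
        t_perm = het * math.log(2.0) - gammaln(tab + 1.0).sum(axis=1)
        hits += int(np.sum(t_perm <= t_obs + 1e-9))
    return (1 + hits) / (1 + n_permutations)


def hwe_test_table(
    table: GenotypeTable,
    level: Level = "length",
    alpha: float = 0.05,
    n_permutations: int = 17000,
    seed: int | None = None,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """HWE exact tests for all autosomal markers, with Bonferroni flags."""
    if markers is None:
        markers = table.markers("autosomal")
    results = []
    for i, marker in enumerate(markers):
        counts = genotype_counts(table, marker, level)
        sub_seed = None if seed is None else (seed + i) % (2**31)
        results.append(hwe_exact_test(counts, n_permutations, sub_seed, marker))
    pvals = {r.marker: r.p_value for r in results}
    threshold, flags = bonferroni(pvals, alpha)
    return pd.DataFrame(
        {
            "marker": [r.marker for r in results],
            "p_value": [r.p_value for r in results],
            "method": [r.method for r in results],
            "n_permutations": [r.n_permutations for r in results],
            "bonferroni_threshold": threshold,
            "deviates": [flags[r.marker] for r in results],
        }
    )


def bonferroni(
    p_values: Mapping[str, float], alpha: float = 0.05
) -> tuple[float, dict[str, bool]]:
    """Threshold alpha/m; a marker is flagged only if p < threshold."""
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / m
    return threshold, {k: p < threshold for k, p in p_values.items()}


def _as_probs(freqs: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(freqs, Mapping):
        p = np.asarray(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p
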