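"""Pairwise population differentiation: Fst (allele identity) and Rst
(repeat-count variance).

Fst between populations with genotype data uses the Weir-Cockerham (1984)
theta: per locus and allele, variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
accumulated, and theta is the ratio of summed a to summed a+b+c across all
loci and alleles.  When only allele-frequency tables are available, the
Nei-Chesser sample-size-corrected Gst stands in (recorded in metadata).

Rst for haploid repeat-count data follows the stepwise-mutation logic:
a one-level AMOVA on squared repeat-count differences yields among- and
within-population variance components per locus, which are summed over loci
before taking the ratio.  Both statistics are invariant under affine
transforms of the repeat counts, as the components scale together.

Negative point estimates (possible for both estimators when true
differentiation is near zero) are floored at 0 in the distance matrix; the
raw values are retained in the matrix metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import Level, label_to_length
from .tables import GenotypeTable

__all__ = [
    "DistanceMatrix",
    "weir_cockerham_theta",
    "nei_fst_from_freqs",
    "slatkin_rst",
    "pairwise_fst",
    "pairwise_rst",
    "nearest_populations",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise population distances.

    ``values`` has negatives floored at 0; ``raw`` keeps the untruncated
    estimates for inspection.
    """

    labels: list[str]
    values: np.ndarray
    raw: np.ndarray | None = None
    statistic: str = ""
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("population labels must be unique")
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative (floor negatives)")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# -- Weir-Cockerham theta ------------------------------------------------


def _wc_components_locus(
    pop_calls: Sequence[Mapping[str, tuple[str, str]]],
) -> tuple[float, float, float]:
    """Summed (a, b, c) over alleles at one locus, Weir & Cockerham 1984."""
    r = len(pop_calls)
    n_i = np.array([len(c) for c in pop_calls], dtype=float)
    if np.any(n_i < 1) or r < 2:
        return 0.0, 0.0, 0.0
    alleles = sorted({a for calls in pop_calls for pair in calls.values() for a in pair})
    nbar = n_i.mean()
    n_total = n_i.sum()
    nc = (n_total - np.sum(n_i**2) / n_total) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.empty(r)
        h_i = np.empty(r)
        for k, calls in enumerate(pop_calls):
            cnt = 0
            het = 0
            for a1, a2 in calls.values():
                cnt += (a1 == allele) + (a2 == allele)
                het += (a1 == allele) != (a2 == allele)
            p_i[k] = cnt / (2 * n_i[k])
            h_i[k] = het / n_i[k]
        pbar = float(np.sum(n_i * p_i) / n_total)
        s2 = float(np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n_i * h_i) / n_total)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def weir_cockerham_theta(
    tables: Sequence[GenotypeTable],
    loci: Sequence[str],
    level: Level = "length",
) -> float:
    """Multi-locus Weir-Cockerham theta across two or more populations."""
    num = den = 0.0
    for locus in loci:
        pop_calls = [t.diploid_calls(locus, level) for t in tables]
        a, b, c = _wc_components_locus(pop_calls)
        num += a
        den += a + b + c
    if den == 0.0:
        return 0.0
    return num / den


def nei_fst_from_freqs(
    pop_freqs: Sequence[Mapping[str, Mapping[str, float]]],
    pop_sizes: Sequence[Mapping[str, int]],
    loci: Sequence[str],
) -> float:
    """Nei-Chesser corrected Gst from per-population frequency tables.

    ``pop_sizes[k][locus]`` is the diploid sample size of population k at
    that locus.  Used when raw genotypes are unavailable.
    """
    hs_sum = ht_sum = 0.0
    r = len(pop_freqs)
    for locus in loci:
        alleles = sorted({a for pf in pop_freqs for a in pf[locus]})
        p = np.array(
            [[pf[locus].get(a, 0.0) for a in alleles] for pf in pop_freqs]
        )
        n = np.array([float(ps[locus]) for ps in pop_sizes])
        n_harm = r / np.sum(1.0 / n)
        hs_hat = float(np.mean(1.0 - np.sum(p**2, axis=1)))
        hs = (2 * n_harm / (2 * n_harm - 1)) * hs_hat
        pbar = p.mean(axis=0)
        ht_hat = 1.0 - float(np.sum(pbar**2))
        ht = ht_hat + hs / (2 * n_harm * r)
        hs_sum += hs
        ht_sum += ht
    if ht_sum == 0.0:
        return 0.0
    return 1.0 - hs_sum / ht_sum


# -- Slatkin Rst ---------------------------------------------------------


def _repeat_counts(
    table: GenotypeTable, locus: str, microvariants: str
) -> np.ndarray | None:
    """Haploid repeat counts at a locus; None if the locus must be skipped."""
    mdef = table.panel[locus]
    if mdef.ploidy_class == "y_multicopy":
        return None
    if mdef.is_y:
        calls = [a for alleles in table.haploid_calls(locus, "length").values() for a in alleles]
    else:
        calls = [a for pair in table.diploid_calls(locus, "length").values() for a in pair]
    values = []
    for label in calls:
        try:
            ce = label_to_length(label, mdef.period)
        except Exception:
            return None
        if "." in ce:
            if microvariants == "skip":
                return None
            ce = ce.split(".")[0]
        values.append(int(ce))
    return np.asarray(values, dtype=float)


def _rst_components_locus(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) from one-level AMOVA on repeat counts."""
    groups = [g for g in groups if g.size > 0]
    d = len(groups)
    n_j = np.array([g.size for g in groups], dtype=float)
    n_total = n_j.sum()
    if d < 2 or n_total <= d:
        return 0.0, 0.0
    pooled = np.concatenate(groups)
    ssd_total = float(np.sum((pooled - pooled.mean()) ** 2))
    ssd_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    ssd_among = ssd_total - ssd_within
    ms_within = ssd_within / (n_total - d)
    ms_among = ssd_among / (d - 1)
    n_prime = (n_total - np.sum(n_j**2) / n_total) / (d - 1)
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n_prime
    return sigma2_among, sigma2_within


def slatkin_rst(
    tables: Sequence[GenotypeTable],
    loci: Sequence[str],
    microvariants: str = "floor",
) -> float:
    """Multi-locus Rst: among / (among + within) with components summed."""
    if microvariants not in ("floor", "skip"):
        raise ValueError("microvariants must be 'floor' or 'skip'")
    among = within = 0.0
    used = 0
    for locus in loci:
        groups = []
        skip = False
        for t in tables:
            g = _repeat_counts(t, locus, microvariants)
            if g is None:
                warnings.warn(f"locus {locus} skipped for Rst (non-numeric or multi-copy)")
                skip = True
                break
            groups.append(g)
        if skip:
            continue
        sa, sw = _rst_components_locus(groups)
        among += sa
        within += sw
        used += 1
    if used == 0:
        raise ValueError("no usable loci for Rst")
    total = among + within
    if total == 0.0:
        return 0.0
    return among / total


# -- pairwise matrices ----------------------------------------------------


def _pairwise(
    pops: Mapping[str, GenotypeTable],
    loci: Sequence[str],
    stat_fn,
    statistic: str,
) -> DistanceMatrix:
    labels = list(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    n = len(labels)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            est = stat_fn(pops[labels[i]], pops[labels[j]])
            raw[i, j] = raw[j, i] = est
    values = np.clip(raw, 0.0, None)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values, raw=raw, statistic=statistic, loci=list(loci))


def _shared_loci(pops: Mapping[str, GenotypeTable], loci, ploidy_class) -> list[str]:
    tables = list(pops.values())
    if loci is None:
        shared = set(tables[0].markers(ploidy_class))
        for t in tables[1:]:
            shared &= set(t.markers(ploidy_class))
        loci = sorted(shared)
    if not loci:
        raise ValueError("no shared loci between populations")
    return list(loci)


def pairwise_fst(
    pops: Mapping[str, GenotypeTable],
    loci: Sequence[str] | None = None,
    level: Level = "length",
) -> DistanceMatrix:
    """Pairwise multi-locus Weir-Cockerham theta between populations."""
    loci = _shared_loci(pops, loci, "autosomal")
    return _pairwise(
        pops,
        loci,
        lambda a, b: weir_cockerham_theta([a, b], loci, level),
        "fst_weir_cockerham",
    )


def pairwise_rst(
    pops: Mapping[str, GenotypeTable],
    loci: Sequence[str] | None = None,
    microvariants: str = "floor",
) -> DistanceMatrix:
    """Pairwise Slatkin Rst from haploid repeat-count data."""
    loci = _shared_loci(pops, loci, None)
    return _pairwise(
        pops,
        loci,
        lambda a, b: slatkin_rst([a, b], loci, microvariants),
        "rst_slatkin",
    )


def nearest_populations(
    matrix: DistanceMatrix, focal: str, k: int | None = None
) -> list[tuple[str, float]]:
    """Neighbors of ``focal`` in ascending distance; ties broken lexically."""
    if focal not in matrix.labels:
        raise KeyError(f"population {focal!r} not in matrix")
    i = matrix.labels.index(focal)
    others = [
        (lab, float(matrix.values[i, j]))
        for j, lab in enumerate(matrix.labels)
        if lab != focal
    ]
    others.sort(key=lambda t: (t[1], t[0]))
    return others[:k] if k is not None else others
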