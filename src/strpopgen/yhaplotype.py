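"""Y-STR haplotype construction and direct-counting diversity statistics.

A Y haplotype is the ordered tuple of a male's alleles over a locus panel;
multi-copy loci (e.g. DYS385a/b) contribute an order-normalized multiset so
that (14, 17) and (17, 14) are the same haplotype.  From the haplotype
frequency spectrum the standard forensic summaries follow:

* HMP — haplotype match probability, sum of squared haplotype frequencies.
* HD  — haplotype diversity, n (1 - HMP) / (n - 1).
* DC  — discrimination capacity, distinct haplotypes / sampled males.
* fraction_unique — singleton haplotypes over distinct haplotypes.

Per-locus haploid gene diversity uses the same n/(n-1)-corrected estimator,
treating a multi-copy locus's normalized multiset as a compound allele.
Kit comparison recomputes the summaries on locus subsets (commercial panel
definitions) over the same male cohort.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .nomenclature import Level
from .tables import GenotypeTable

__all__ = [
    "Haplotype",
    "HaplotypeStats",
    "KitDef",
    "build_haplotypes",
    "haplotype_stats",
    "hd_from_hmp",
    "haploid_locus_gd",
    "kit_comparison",
]

# A haplotype is a tuple over loci; each component is itself a tuple of
# allele labels (length 1 for single-copy loci, >=2 for multi-copy).
Haplotype = tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class KitDef:
    """A commercial typing kit: a name and its locus subset."""

    name: str
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError(f"kit {self.name!r} has no loci")


@dataclass(frozen=True)
class HaplotypeStats:
    n_males: int
    n_haplotypes: int
    hd: float
    hmp: float
    dc: float
    fraction_unique: float
    level: Level
    n_excluded: int = 0


def build_haplotypes(
    table: GenotypeTable,
    loci: Sequence[str] | None = None,
    level: Level = "length",
) -> tuple[list[Haplotype], int]:
    """One haplotype per male with complete calls at every requested locus.

    Males missing any component are excluded (haplotypes must be complete to
    compare); the count of exclusions is returned alongside.  Raises if a
    non-Y locus is requested.
    """
    if loci is None:
        loci = table.markers("y")
    for locus in loci:
        if not table.panel[locus].is_y:
            raise ValueError(f"{locus} is not a Y marker")
    per_locus = {locus: table.haploid_calls(locus, level) for locus in loci}
    males = table.males
    haplotypes: list[Haplotype] = []
    excluded = 0
    for s in males:
        try:
            hap = tuple(per_locus[locus][s] for locus in loci)
        except KeyError:
            excluded += 1
            continue
        haplotypes.append(hap)
    return haplotypes, excluded


def hd_from_hmp(hmp: float, n: int) -> float:
    """Haplotype diversity from the match probability: n (1 - HMP) / (n - 1)."""
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    if not 0.0 <= hmp <= 1.0:
        raise ValueError(f"HMP {hmp} outside [0, 1]")
    return n * (1.0 - hmp) / (n - 1)


def haplotype_stats(
    haplotypes: Sequence[Haplotype], level: Level = "length"
) -> HaplotypeStats:
    """Direct-counting HD, HMP, DC and unique fraction of a haplotype list."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    spectrum = Counter(haplotypes)
    hmp = math.fsum((c / n) ** 2 for c in spectrum.values())
    n_distinct = len(spectrum)
    singletons = sum(1 for c in spectrum.values() if c == 1)
    return HaplotypeStats(
        n_males=n,
        n_haplotypes=n_distinct,
        hd=hd_from_hmp(hmp, n),
        hmp=hmp,
        dc=n_distinct / n,
        fraction_unique=singletons / n_distinct,
        level=level,
    )


def haploid_locus_gd(
    table: GenotypeTable, locus: str, level: Level = "length"
) -> float:
    """Haploid gene diversity n (1 - sum p^2) / (n - 1) at one Y locus.

    n is the number of typed males at this locus; a multi-copy locus's
    normalized allele multiset counts as a single compound allele.
    """
    calls = table.haploid_calls(locus, level)
    n = len(calls)
    if n < 2:
        raise ValueError(f"need >= 2 typed males at {locus}")
    spectrum = Counter(calls.values())
    sum_p2 = math.fsum((c / n) ** 2 for c in spectrum.values())
    return n * (1.0 - sum_p2) / (n - 1)


def kit_comparison(
    table: GenotypeTable,
    kits: Sequence[KitDef],
    level: Level = "length",
) -> pd.DataFrame:
    """HD/HMP/DC per kit on the same male cohort, sortable by DC."""
    rows = []
    for kit in kits:
        haps, excluded = build_haplotypes(table, kit.loci, level)
        stats = haplotype_stats(haps, level)
        rows.append(
            {
                "kit": kit.name,
                "n_loci": len(kit.loci),
                "n_males": stats.n_males,
                "n_excluded": excluded,
                "n_haplotypes": stats.n_haplotypes,
                "hd": stats.hd,
                "hmp": stats.hmp,
                "dc": stats.dc,
                "fraction_unique": stats.fraction_unique,
            }
        )
    return pd.DataFrame(rows)
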