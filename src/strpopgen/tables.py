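"""Genotype tables: samples x markers at length or sequence resolution.

The canonical interchange is a wide table — one row per sample, two allele
columns per autosomal marker (``M.1``/``M.2``), one column per Y marker
(multi-copy loci hold comma-joined labels in a single cell).  Cells contain
allele labels in either dialect: plain CE designations (``"9"``, ``"9.3"``)
or bracket notation (``"[TCTA]4[TCTG]6 TCA"``); missing data is an empty
cell.  A ``sex`` column (M/F) is required whenever Y markers are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .nomenclature import (
    Level,
    MarkerDef,
    NomenclatureError,
    allele_sort_key,
    label_to_length,
    normalize_label,
)

__all__ = ["GenotypeTable", "Panel"]

Panel = dict[str, MarkerDef]


def _convert(label: str, level: Level, period: int) -> str:
    if level == "length":
        return label_to_length(label, period)
    return label


@dataclass
class GenotypeTable:
    """Wide genotype table with a marker panel and optional sex column.

    ``diploid`` holds, per autosomal marker, a mapping sample -> (a1, a2)
    label pair; ``haploid`` holds, per Y marker, sample -> sorted tuple of
    labels (one for single-copy loci, two or more for multi-copy loci).
    Labels are stored normalized (canonical bracket form or CE string); the
    stored resolution is whatever the source provided, and accessors project
    to ``length`` on demand.
    """

    panel: Panel
    samples: list[str]
    sex: dict[str, str] = field(default_factory=dict)
    diploid: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    haploid: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y_markers = [m for m in self.panel.values() if m.is_y]
        if y_markers and not self.sex:
            raise ValueError("sex column required when Y markers are present")
        for s, sx in self.sex.items():
            if sx not in ("M", "F"):
                raise ValueError(f"sample {s}: sex must be M or F, got {sx!r}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        panel: Panel,
        samples: Sequence[str],
        sex: Mapping[str, str] | None = None,
        diploid: Mapping[str, Mapping[str, tuple[str, str]]] | None = None,
        haploid: Mapping[str, Mapping[str, tuple[str, ...]]] | None = None,
        normalize: bool = True,
    ) -> "GenotypeTable":
        dip: dict[str, dict[str, tuple[str, str]]] = {}
        hap: dict[str, dict[str, tuple[str, ...]]] = {}
        for marker, calls in (diploid or {}).items():
            period = panel[marker].period
            dip[marker] = {
                s: tuple(normalize_label(a, period) if normalize else a for a in pair)  # type: ignore[misc]
                for s, pair in calls.items()
            }
        for marker, calls in (haploid or {}).items():
            period = panel[marker].period
            hap[marker] = {
                s: cls._sort_multiset(
                    [normalize_label(a, period) if normalize else a for a in alleles],
                    period,
                )
                for s, alleles in calls.items()
            }
        return cls(dict(panel), list(samples), dict(sex or {}), dip, hap)

    @staticmethod
    def _sort_multiset(labels: Iterable[str], period: int) -> tuple[str, ...]:
        return tuple(sorted(labels, key=lambda a: allele_sort_key(a, period)))

    # -- accessors --------------------------------------------------------

    @property
    def males(self) -> list[str]:
        return [s for s in self.samples if self.sex.get(s) == "M"]

    def markers(self, ploidy_class: str | None = None) -> list[str]:
        if ploidy_class is None:
            return list(self.panel)
        if ploidy_class == "y":
            return [m for m, d in self.panel.items() if d.is_y]
        return [
            m for m, d in self.panel.items() if d.ploidy_class == ploidy_class
        ]

    def diploid_calls(self, marker: str, level: Level = "sequence") -> dict[str, tuple[str, str]]:
        """Typed samples' genotypes at an autosomal marker (missing dropped)."""
        mdef = self._require(marker)
        if mdef.is_y:
            raise ValueError(f"{marker} is a Y marker; use haploid_calls")
        calls = self.diploid.get(marker, {})
        period = mdef.period
        return {
            s: tuple(_convert(a, level, period) for a in pair)  # type: ignore[return-value]
            for s, pair in calls.items()
        }

    def haploid_calls(self, marker: str, level: Level = "sequence") -> dict[str, tuple[str, ...]]:
        """Typed males' allele multisets at a Y marker, order-normalized."""
        mdef = self._require(marker)
        if not mdef.is_y:
            raise ValueError(f"{marker} is autosomal; use diploid_calls")
        calls = self.haploid.get(marker, {})
        period = mdef.period
        return {
            s: self._sort_multiset(
                (_convert(a, level, period) for a in alleles), period
            )
            for s, alleles in calls.items()
        }

    def observed_alleles(self, marker: str, level: Level = "sequence") -> set[str]:
        """Distinct allele labels observed at least once at a marker."""
        mdef = self._require(marker)
        out: set[str] = set()
        if mdef.is_y:
            for alleles in self.haploid_calls(marker, level).values():
                out.update(alleles)
        else:
            for pair in self.diploid_calls(marker, level).values():
                out.update(pair)
        return out

    def n_typed(self, marker: str) -> int:
        mdef = self._require(marker)
        store = self.haploid if mdef.is_y else self.diploid
        return len(store.get(marker, {}))

    def _require(self, marker: str) -> MarkerDef:
        if marker not in self.panel:
            raise KeyError(f"unknown marker {marker!r}")
        return self.panel[marker]

    # -- level projection --------------------------------------------------

    def collapse_to_length(self) -> "GenotypeTable":
        """New table with every cell projected to its CE designation."""
        dip = {
            m: self.diploid_calls(m, "length") for m in self.diploid
        }
        hap = {
            m: self.haploid_calls(m, "length") for m in self.haploid
        }
        return GenotypeTable(dict(self.panel), list(self.samples), dict(self.sex), dip, hap)

    # -- wide-frame serialization ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame matching the interchange CSV layout."""
        cols: dict[str, list[str]] = {}
        if self.sex:
            cols["sex"] = [self.sex.get(s, "") for s in self.samples]
        for marker, mdef in self.panel.items():
            if mdef.is_y:
                calls = self.haploid.get(marker, {})
                cols[marker] = [
                    ",".join(calls[s]) if s in calls else "" for s in self.samples
                ]
            else:
                calls = self.diploid.get(marker, {})
                cols[f"{marker}.1"] = [
                    calls[s][0] if s in calls else "" for s in self.samples
                ]
                cols[f"{marker}.2"] = [
                    calls[s][1] if s in calls else "" for s in self.samples
                ]
        df = pd.DataFrame(cols, index=pd.Index(self.samples, name="sample"))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel: Panel) -> "GenotypeTable":
        """Inverse of :meth:`to_frame`; empty cells become missing calls."""
        samples = [str(s) for s in df.index]
        sex: dict[str, str] = {}
        if "sex" in df.columns:
            for s, v in zip(samples, df["sex"].astype(str)):
                v = v.strip()
                if v:
                    sex[s] = v
        diploid: dict[str, dict[str, tuple[str, str]]] = {}
        haploid: dict[str, dict[str, tuple[str, ...]]] = {}
        for marker, mdef in panel.items():
            if mdef.is_y:
                if marker not in df.columns:
                    continue
                calls: dict[str, tuple[str, ...]] = {}
                for s, cell in zip(samples, df[marker]):
                    cell = "" if pd.isna(cell) else str(cell).strip()
                    if not cell:
                        continue
                    if sex.get(s) == "F":
                        raise ValueError(
                            f"female sample {s} has Y calls at {marker}"
                        )
                    labels = [p.strip() for p in cell.split(",") if p.strip()]
                    calls[s] = tuple(labels)
                haploid[marker] = calls
            else:
                c1, c2 = f"{marker}.1", f"{marker}.2"
                if c1 not in df.columns or c2 not in df.columns:
                    continue
                dcalls: dict[str, tuple[str, str]] = {}
                for s, a1, a2 in zip(samples, df[c1], df[c2]):
                    a1 = "" if pd.isna(a1) else str(a1).strip()
                    a2 = "" if pd.isna(a2) else str(a2).strip()
                    if not a1 or not a2:
                        continue
                    dcalls[s] = (a1, a2)
                diploid[marker] = dcalls
        return cls.from_calls(panel, samples, sex, diploid, haploid)
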