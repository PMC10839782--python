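"""Sequence-level STR allele nomenclature.

Massively-parallel sequencing resolves short-tandem-repeat alleles at the
sequence level: two alleles with the same total repeat count (hence the same
capillary-electrophoresis designation, e.g. ``10``) may differ in their
internal motif arrangement (``[TCTA]4[TCTG]6`` vs ``[TCTA]10``).  This module
provides the data model for both resolutions:

* :class:`RepeatStructure` — ordered motif blocks plus an optional trailing
  partial repeat unit; the sequence-level identity of an allele.
* CE designation — the length-level label, total repeat count with a ``.k``
  microvariant suffix for ``k`` leftover bases (``9.3``).
* bracket-notation parsing/emission, collapse of sequence alleles to length
  alleles, and allele-diversity accounting between the two levels.

Only the repeat region is modelled; flanking-region variation is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

__all__ = [
    "MotifBlock",
    "RepeatStructure",
    "SequenceAllele",
    "LengthAllele",
    "MarkerDef",
    "NomenclatureError",
    "parse_bracket_notation",
    "emit_bracket_notation",
    "ce_designation",
    "collapse_to_length",
    "label_to_length",
    "is_bracket_notation",
    "allele_sort_key",
    "allele_inventory",
    "allele_growth",
    "AlleleInventory",
]

PloidyClass = Literal["autosomal", "y_single", "y_multicopy"]
Level = Literal["length", "sequence"]

_MOTIF_RE = re.compile(r"[ACGT]{2,6}")
_TOKEN_RE = re.compile(r"\[([A-Za-z]+)\]\s*(\d+)|([A-Za-z]+)|(\S)")


class NomenclatureError(ValueError):
    """Raised for malformed bracket notation or invalid repeat structures."""


@dataclass(frozen=True)
class MotifBlock:
    """A run of ``count`` consecutive copies of ``motif`` (2-6 bp, ACGT)."""

    motif: str
    count: int

    def __post_init__(self) -> None:
        if not _MOTIF_RE.fullmatch(self.motif):
            raise NomenclatureError(
                f"invalid motif {self.motif!r}: need 2-6 bases from ACGT"
            )
        if not isinstance(self.count, int) or self.count < 1:
            raise NomenclatureError(f"invalid block count {self.count!r}")


@dataclass(frozen=True)
class RepeatStructure:
    """Ordered motif blocks plus a trailing partial unit (< one period)."""

    blocks: tuple[MotifBlock, ...]
    partial: str = ""
    period: int = 4

    def __post_init__(self) -> None:
        if not self.blocks:
            raise NomenclatureError("repeat structure needs at least one block")
        if not 2 <= self.period <= 6:
            raise NomenclatureError(f"period {self.period} outside 2..6")
        if self.partial:
            if not re.fullmatch(r"[ACGT]+", self.partial):
                raise NomenclatureError(f"invalid partial unit {self.partial!r}")
            if len(self.partial) >= self.period:
                raise NomenclatureError(
                    f"partial unit {self.partial!r} has length "
                    f">= period {self.period}"
                )

    @property
    def total_repeats(self) -> int:
        return sum(b.count for b in self.blocks)

    def sequence(self) -> str:
        """Concatenated nucleotide sequence of the repeat region."""
        return "".join(b.motif * b.count for b in self.blocks) + self.partial


@dataclass(frozen=True)
class SequenceAllele:
    """A sequence-resolved allele at a marker; equality by structure."""

    marker: str
    structure: RepeatStructure
    ce_label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        expected = ce_designation(self.structure)
        if not self.ce_label:
            object.__setattr__(self, "ce_label", expected)
        elif self.ce_label != expected:
            raise NomenclatureError(
                f"ce_label {self.ce_label!r} inconsistent with structure "
                f"(expected {expected!r})"
            )


@dataclass(frozen=True)
class LengthAllele:
    """A length-resolved (CE) allele; equality by (marker, ce_label)."""

    marker: str
    ce_label: str

    def __post_init__(self) -> None:
        m = re.fullmatch(r"(\d+)(?:\.(\d+))?", self.ce_label)
        if not m:
            raise NomenclatureError(f"invalid CE designation {self.ce_label!r}")


@dataclass(frozen=True)
class MarkerDef:
    """Panel entry: marker name, ploidy class and repeat-unit length."""

    name: str
    ploidy_class: PloidyClass
    period: int = 4

    def __post_init__(self) -> None:
        if not 2 <= self.period <= 6:
            raise NomenclatureError(
                f"marker {self.name}: period {self.period} outside 2..6"
            )

    @property
    def is_y(self) -> bool:
        return self.ploidy_class in ("y_single", "y_multicopy")


def parse_bracket_notation(text: str, period: int = 4) -> RepeatStructure:
    """Parse ``"[TCTA]4[TCTG]6 TCA"`` into a :class:`RepeatStructure`.

    Whitespace between blocks and before the trailing partial unit is
    ignored.  A bare run of bases after the last block is the partial unit
    (a microvariant); its length must be below the marker period.
    """
    blocks: list[MotifBlock] = []
    partial = ""
    pos = 0
    stripped = text.strip()
    if not stripped:
        raise NomenclatureError("empty allele string")
    for m in _TOKEN_RE.finditer(stripped):
        motif, count, bare, junk = m.group(1), m.group(2), m.group(3), m.group(4)
        if junk is not None:
            raise NomenclatureError(
                f"malformed token {junk!r} at position {m.start()} in {text!r}"
            )
        if bare is not None:
            if partial:
                raise NomenclatureError(
                    f"unexpected token {bare!r} after partial unit in {text!r}"
                )
            bare = bare.upper()
            if not re.fullmatch(r"[ACGT]+", bare):
                raise NomenclatureError(f"non-ACGT characters in {bare!r}")
            if len(bare) >= period:
                raise NomenclatureError(
                    f"partial unit {bare!r} not shorter than period {period}"
                )
            partial = bare
            continue
        if partial:
            raise NomenclatureError(
                f"block [{motif}]{count} after partial unit in {text!r}"
            )
        motif = motif.upper()
        if not _MOTIF_RE.fullmatch(motif):
            raise NomenclatureError(f"invalid motif [{motif}] in {text!r}")
        blocks.append(MotifBlock(motif, int(count)))
        pos = m.end()
    del pos
    if not blocks:
        raise NomenclatureError(f"no [MOTIF]n blocks found in {text!r}")
    return RepeatStructure(tuple(blocks), partial, period)


def emit_bracket_notation(structure: RepeatStructure) -> str:
    """Canonical bracket string: blocks abutting, partial after one space."""
    s = "".join(f"[{b.motif}]{b.count}" for b in structure.blocks)
    if structure.partial:
        s += f" {structure.partial}"
    return s


def ce_designation(structure: RepeatStructure) -> str:
    """CE label: total block repeats, ``.k`` suffix for a k-base partial."""
    n = structure.total_repeats
    if structure.partial:
        return f"{n}.{len(structure.partial)}"
    return str(n)


def collapse_to_length(allele: SequenceAllele | LengthAllele) -> LengthAllele:
    """Project an allele to length resolution (identity on length alleles)."""
    if isinstance(allele, LengthAllele):
        return allele
    return LengthAllele(allele.marker, allele.ce_label)


def is_bracket_notation(label: str) -> bool:
    return "[" in label


def label_to_length(label: str, period: int = 4) -> str:
    """Map an allele label of either dialect to its CE designation.

    Bracket-notation labels are parsed and collapsed; plain CE labels are
    returned unchanged (after validation).
    """
    label = label.strip()
    if is_bracket_notation(label):
        return ce_designation(parse_bracket_notation(label, period))
    if not re.fullmatch(r"\d+(?:\.\d+)?", label):
        raise NomenclatureError(f"invalid allele label {label!r}")
    return label


def normalize_label(label: str, period: int = 4) -> str:
    """Canonical form of a label: re-emitted brackets, or the CE string."""
    label = label.strip()
    if is_bracket_notation(label):
        return emit_bracket_notation(parse_bracket_notation(label, period))
    if not re.fullmatch(r"\d+(?:\.\d+)?", label):
        raise NomenclatureError(f"invalid allele label {label!r}")
    return label


def allele_sort_key(label: str, period: int = 6) -> tuple[float, str]:
    """Sort alleles numerically by CE value, then lexically by label.

    Parsing here is permissive (period 6, the largest legal repeat unit):
    the key only orders labels, validation happens at table construction.
    """
    ce = label_to_length(label, 6)
    return (float(ce), label)


@dataclass
class AlleleInventory:
    """Distinct-allele counts per marker plus totals by marker class."""

    level: Level
    per_marker: dict[str, int]
    totals: dict[str, int]  # keys: "autosomal", "y", "all"


def allele_inventory(table, level: Level) -> AlleleInventory:
    """Count distinct alleles observed at least once, per marker.

    ``table`` is a :class:`~strpopgen.tables.GenotypeTable`.  At sequence
    level every distinct normalized label counts; at length level labels are
    collapsed to CE designations first, so the sequence-level count is >= the
    length-level count for every marker.
    """
    if level not in ("length", "sequence"):
        raise ValueError(f"unknown level {level!r}")
    per_marker: dict[str, int] = {}
    totals = {"autosomal": 0, "y": 0, "all": 0}
    for mdef in table.panel.values():
        alleles = table.observed_alleles(mdef.name, level)
        per_marker[mdef.name] = len(alleles)
        cls = "autosomal" if mdef.ploidy_class == "autosomal" else "y"
        totals[cls] += len(alleles)
        totals["all"] += len(alleles)
    return AlleleInventory(level, per_marker, totals)


def allele_growth(
    len_counts: Mapping[str, int], seq_counts: Mapping[str, int]
):
    """Per-marker allele gain from sequence resolution, with growth rate %.

    Returns a DataFrame with columns ``marker, n_length, n_sequence, added,
    growth_pct, doubled`` (``doubled`` flags growth above 100%).  Raises if a
    marker has a zero length-level count (marker absent from the table).
    """
    import pandas as pd

    rows = []
    for marker in len_counts:
        nl = len_counts[marker]
        ns = seq_counts.get(marker, 0)
        if nl == 0:
            raise ValueError(f"marker {marker!r} has no length-level alleles")
        if ns < nl:
            raise ValueError(
                f"marker {marker!r}: sequence count {ns} < length count {nl}"
            )
        added = ns - nl
        growth = 100.0 * added / nl
        rows.append((marker, nl, ns, added, growth, growth > 100.0))
    return pd.DataFrame(
        rows,
        columns=["marker", "n_length", "n_sequence", "added", "growth_pct", "doubled"],
    )
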