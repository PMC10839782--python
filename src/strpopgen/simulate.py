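"""Synthetic STR populations with the statistical structure of real panels.

Generates genotype tables that exercise every downstream stage without any
raw data: 52 diploid autosomal markers and 81 haploid Y markers (four of
them multi-copy a/b loci), sequence-level alleles in bracket notation with
iso-length variants nested inside length alleles, Hardy-Weinberg genotypes
with an optional inbreeding departure, founder-lineage Y haplotypes with
single-step mutation, and Balding-Nichols divergence between populations at
a chosen target Fst.

Default conditions mirror a typical single-population forensic study: 628
samples (547 males, 81 females), autosomal allele counts in 6..25 with mean
near 10.7, Y single-copy counts in 1..13 with two monomorphic loci, and an
iso-length variant multiplicity of P(1..4)=(0.60, 0.25, 0.10, 0.05) so the
sequence level carries about 1.6x the length-level allele count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .nomenclature import (
    MarkerDef,
    MotifBlock,
    RepeatStructure,
    emit_bracket_notation,
    label_to_length,
    parse_bracket_notation,
)
from .tables import GenotypeTable, Panel

__all__ = [
    "SimConfig",
    "default_panel",
    "sample_allele_frequencies",
    "split_into_sequence_variants",
    "build_panel_frequencies",
    "simulate_autosomal_genotypes",
    "simulate_y_haplotypes",
    "simulate_diverged_populations",
    "generate_dataset",
]

_AUTOSOMAL_MARKERS = [
    "CSF1PO", "D10S1248", "D10S1435", "D11S2368", "D11S4463", "D12ATA63",
    "D12S391", "D13S317", "D13S325", "D14S1434", "D15S659", "D16S539",
    "D17S1290", "D17S1301", "D18S51", "D18S535", "D19S253", "D19S433",
    "D1GATA113", "D1S1656", "D1S1677", "D20S470", "D20S482", "D21S11",
    "D22GATA198B05", "D22S1045", "D2S1338", "D2S441", "D3S1358", "D3S3045",
    "D3S4529", "D4S2366", "D4S2408", "D5S2500", "D5S818", "D6S1017",
    "D6S1043", "D6S474", "D6S477", "D7S1517", "D7S3048", "D7S820",
    "D8S1132", "D8S1179", "D9S1122", "D9S925", "FGA", "Penta-D", "Penta-E",
    "TH01", "TPOX", "vWA",
]

_Y_MULTICOPY = ["DYF387S1a/b", "DYF404S1a/b", "DYS385a/b", "DYS527a/b"]

_Y_SINGLE = [
    "DYS572", "DYS19", "DYS388", "DYS389I", "DYS389II", "DYS390", "DYS391",
    "DYS392", "DYS393", "DYS434", "DYS435", "DYS437", "DYS438", "DYS439",
    "DYS443", "DYS444", "DYS447", "DYS448", "DYS449", "DYS450", "DYS453",
    "DYS454", "DYS455", "DYS456", "DYS458", "DYS460", "DYS472", "DYS476",
    "DYS481", "DYS485", "DYS502", "DYS505", "DYS508", "DYS510", "DYS511",
    "DYS512", "DYS513", "DYS518", "DYS522", "DYS530", "DYS531", "DYS533",
    "DYS538", "DYS541", "DYS549", "DYS552", "DYS556", "DYS557", "DYS565",
    "DYS568", "DYS570", "DYS571", "DYS573", "DYS576", "DYS578", "DYS585",
    "DYS587", "DYS590", "DYS593", "DYS596", "DYS612", "DYS613", "DYS616",
    "DYS617", "DYS622", "DYS626", "DYS627", "DYS630", "DYS635", "DYS638",
    "DYS640", "DYS641", "DYS643", "DYS645", "DYS722", "GATA A10", "GATA H4",
]

# non-tetranucleotide exceptions; everything else is period 4
_PERIODS = {"Penta-D": 5, "Penta-E": 5, "D22S1045": 3, "DYS392": 3, "DYS388": 3, "DYS481": 3}

# loci kept monomorphic by default (real panels carry a couple of
# near-invariant Y loci whose gene diversity is zero)
_MONOMORPHIC_Y = ("DYS502", "DYS613")

_MOTIF_POOLS = {
    2: ["CA", "GT", "TG", "AC"],
    3: ["TCT", "ATT", "AAG", "TAT"],
    4: ["AGAT", "TCTA", "GATA", "TCTG", "AGAA", "GAAA", "TAGA", "GGAA"],
    5: ["AAAGA", "AAGAA", "AGAAA", "ATCTC"],
    6: ["AGTACA", "TCTATC", "GATAGA", "ACAGTA"],
}


def default_panel() -> Panel:
    """The 52 autosomal + 81 Y marker panel used throughout the package."""
    panel: Panel = {}
    for name in _AUTOSOMAL_MARKERS:
        panel[name] = MarkerDef(name, "autosomal", _PERIODS.get(name, 4))
    for name in _Y_MULTICOPY:
        panel[name] = MarkerDef(name, "y_multicopy", _PERIODS.get(name, 4))
    for name in _Y_SINGLE:
        panel[name] = MarkerDef(name, "y_single", _PERIODS.get(name, 4))
    return panel


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic single-population dataset."""

    n_samples: int = 628
    n_males: int = 547
    panel: Panel | None = None
    autosomal_allele_range: tuple[int, int] = (6, 25)
    y_allele_range: tuple[int, int] = (1, 13)
    y_multicopy_allele_range: tuple[int, int] = (8, 14)
    concentration: float = 1.5
    variant_dist: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)  # P(1..4 variants)
    microvariant_prob: float = 0.15
    inbreeding_f: float = 0.0
    n_founders: int = 400
    y_mutation_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError("inbreeding F must be in [0, 1)")
        if not 0 <= self.n_males <= self.n_samples:
            raise ValueError("n_males must be within n_samples")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_allele_frequencies(k: int, concentration: float = 1.5, seed=None) -> np.ndarray:
    """A symmetric-Dirichlet frequency vector over k alleles (sums to 1)."""
    if k < 1:
        raise ValueError("need at least one allele")
    if k == 1:
        return np.array([1.0])
    rng = _rng(seed)
    p = rng.dirichlet(np.full(k, concentration))
    # Dirichlet draws are a.s. positive; guard against float underflow
    p = np.clip(p, 1e-12, None)
    return p / p.sum()


def _draw_allele_count(rng: np.random.Generator, lo: int, hi: int, mean_frac: float) -> int:
    """Integer in [lo, hi], lo + Binomial(hi-lo, mean_frac): low-skewed."""
    return int(lo + rng.binomial(hi - lo, mean_frac))


def _build_length_labels(
    rng: np.random.Generator, k: int, period: int, microvariant_prob: float
) -> list[str]:
    start = int(rng.integers(7, 12))
    labels = [str(start + i) for i in range(k)]
    if k >= 3 and rng.random() < microvariant_prob:
        # turn one non-terminal allele into an n.(period-1) microvariant
        i = int(rng.integers(1, k - 1))
        labels[i] = f"{labels[i]}.{period - 1}"
    return labels


def _variant_structures(
    ce_label: str, n_variants: int, period: int, motifs: Sequence[str]
) -> list[str]:
    """Distinct bracket-notation strings all collapsing to ``ce_label``.

    Variant j moves j repeat units from the primary motif block to a
    secondary one; a microvariant CE keeps its partial unit in every
    variant.
    """
    if "." in ce_label:
        n_str, k_str = ce_label.split(".")
        n, k_part = int(n_str), int(k_str)
        partial = motifs[0][:k_part]
    else:
        n, partial = int(ce_label), ""
    out = []
    for j in range(n_variants):
        if j == 0:
            blocks = (MotifBlock(motifs[0], n),)
        else:
            if n - j < 1:
                break
            blocks = (MotifBlock(motifs[0], n - j), MotifBlock(motifs[1], j))
        out.append(emit_bracket_notation(RepeatStructure(blocks, partial, period)))
    return out


def split_into_sequence_variants(
    length_freqs: Mapping[str, float],
    variant_spec,
    seed=None,
    period: int = 4,
    motifs: Sequence[str] | None = None,
    concentration: float = 2.0,
) -> dict[str, tuple[str, float]]:
    """Partition each length allele's frequency across iso-length variants.

    ``variant_spec`` is either a probability vector over 1..m variants per
    length allele, or a mapping length-label -> variant count.  Returns
    sequence-label -> (parent length label, frequency); collapsing the
    output recovers the input frequencies exactly (sub-frequencies are
    renormalized Dirichlet shares of the parent mass).
    """
    rng = _rng(seed)
    if motifs is None:
        motifs = _MOTIF_POOLS[period][:2]
    out: dict[str, tuple[str, float]] = {}
    for ce_label, p in length_freqs.items():
        if isinstance(variant_spec, Mapping):
            v = int(variant_spec[ce_label])
        else:
            spec = np.asarray(variant_spec, dtype=float)
            v = int(rng.choice(np.arange(1, len(spec) + 1), p=spec / spec.sum()))
        if v < 1:
            raise ValueError(f"variant spec assigns 0 variants to {ce_label!r}")
        seq_labels = _variant_structures(ce_label, v, period, motifs)
        v = len(seq_labels)
        if v == 1:
            shares = np.array([1.0])
        else:
            shares = rng.dirichlet(np.full(v, concentration))
            shares = np.clip(shares, 1e-12, None)
            shares = shares / shares.sum()
        # exact conservation: last share takes the residual
        acc = 0.0
        for i, lab in enumerate(seq_labels):
            share = p - acc if i == v - 1 else p * float(shares[i])
            acc += share
            out[lab] = (ce_label, share)
    return out


def build_panel_frequencies(config: SimConfig, seed=None) -> dict[str, dict[str, float]]:
    """Sequence-level allele frequencies for every marker in the panel."""
    rng = _rng(config.seed if seed is None else seed)
    panel = config.panel or default_panel()
    freqs: dict[str, dict[str, float]] = {}
    for name, mdef in panel.items():
        if mdef.ploidy_class == "autosomal":
            lo, hi = config.autosomal_allele_range
            k = _draw_allele_count(rng, lo, hi, 0.25)
            mv = config.microvariant_prob
        elif mdef.ploidy_class == "y_multicopy":
            lo, hi = config.y_multicopy_allele_range
            k = _draw_allele_count(rng, lo, hi, 0.5)
            mv = 0.05
        else:
            lo, hi = config.y_allele_range
            k = _draw_allele_count(rng, lo, hi, 0.4)
            mv = 0.05
        if name in _MONOMORPHIC_Y:
            k = 1
        labels = _build_length_labels(rng, k, mdef.period, mv)
        p_len = sample_allele_frequencies(k, config.concentration, rng)
        length_freqs = dict(zip(labels, p_len.tolist()))
        pool = _MOTIF_POOLS[mdef.period]
        m0 = int(rng.integers(0, len(pool)))
        motifs = [pool[m0], pool[(m0 + 1) % len(pool)]]
        nested = split_into_sequence_variants(
            length_freqs, config.variant_dist, rng, mdef.period, motifs
        )
        freqs[name] = {lab: f for lab, (_, f) in nested.items()}
    return freqs


def simulate_autosomal_genotypes(
    freqs: Mapping[str, float], n: int, F: float = 0.0, seed=None
) -> list[tuple[str, str]]:
    """Diploid genotypes under HWE, or with inbreeding excess F.

    With probability F the two gene copies are identical by descent (one
    draw duplicated), giving P(aa) = p^2 + F p (1 - p); with F = 0 the two
    copies are independent draws from the allele frequencies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= F < 1.0:
        raise ValueError("F must be in [0, 1)")
    rng = _rng(seed)
    labels = list(freqs.keys())
    p = np.asarray(list(freqs.values()), dtype=float)
    p = p / p.sum()
    a1 = rng.choice(len(labels), size=n, p=p)
    a2 = rng.choice(len(labels), size=n, p=p)
    if F > 0.0:
        ibd = rng.random(n) < F
        a2 = np.where(ibd, a1, a2)
    return [(labels[i], labels[j]) for i, j in zip(a1, a2)]


def _mutate_label(label: str, period: int, rng: np.random.Generator) -> str:
    """Single-step repeat-count mutation (+1/-1 on the first motif block)."""
    step = 1 if rng.random() < 0.5 else -1
    if "[" in label:
        s = parse_bracket_notation(label, period)
        first = s.blocks[0]
        new_count = max(1, first.count + step)
        blocks = (MotifBlock(first.motif, new_count),) + s.blocks[1:]
        return emit_bracket_notation(RepeatStructure(blocks, s.partial, period))
    ce = label_to_length(label, period)
    if "." in ce:
        n_str, k_str = ce.split(".")
        return f"{max(1, int(n_str) + step)}.{k_str}"
    return str(max(1, int(ce) + step))


def simulate_y_haplotypes(
    freqs: Mapping[str, Mapping[str, float]],
    n_males: int,
    seed=None,
    panel: Panel | None = None,
    n_founders: int | None = 400,
    mutation_rate: float = 0.002,
) -> dict[str, dict[str, tuple[str, ...]]]:
    """Haploid Y calls for ``n_males`` males: marker -> sample -> alleles.

    With ``n_founders`` set, a founder-lineage model is used: each founder
    haplotype is drawn locus-wise from the frequencies, each male copies a
    uniformly chosen founder, and every allele copy then mutates by a
    single repeat step with probability ``mutation_rate``.  Loci are thereby
    dependent, as in real patrilineages.  With ``n_founders=None`` loci are
    drawn independently per male.  Multi-copy loci yield unordered pairs.
    """
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    rng = _rng(seed)
    panel = panel or default_panel()
    y_loci = [m for m in freqs if panel[m].is_y]
    if len(y_loci) != len(freqs):
        bad = sorted(set(freqs) - set(y_loci))
        raise ValueError(f"non-Y markers passed to simulate_y_haplotypes: {bad}")

    def draw_locus(marker: str, size: int) -> np.ndarray:
        fmap = freqs[marker]
        labels = list(fmap.keys())
        p = np.asarray(list(fmap.values()), dtype=float)
        p = p / p.sum()
        return rng.choice(len(labels), size=size, p=p)

    samples = [f"M{i + 1:04d}" for i in range(n_males)]
    out: dict[str, dict[str, tuple[str, ...]]] = {m: {} for m in y_loci}
    if n_founders is None:
        assignment = None
    else:
        assignment = rng.integers(0, n_founders, size=n_males)
    for marker in y_loci:
        mdef = panel[marker]
        copies = 2 if mdef.ploidy_class == "y_multicopy" else 1
        labels = list(freqs[marker].keys())
        if assignment is None:
            idx = draw_locus(marker, (n_males, copies))
        else:
            founder_alleles = draw_locus(marker, (n_founders, copies))
            idx = founder_alleles[assignment]
        for si, s in enumerate(samples):
            alleles = []
            for c in range(copies):
                lab = labels[int(idx[si, c]) if idx.ndim == 2 else int(idx[si])]
                if mutation_rate > 0.0 and rng.random() < mutation_rate:
                    lab = _mutate_label(lab, mdef.period, rng)
                alleles.append(lab)
            out[marker][s] = tuple(alleles)
    return out


def simulate_diverged_populations(
    ancestral_freqs: Mapping[str, Mapping[str, float]],
    f_div: float,
    n_per_pop: int,
    n_pops: int = 2,
    ploidy: int = 2,
    seed=None,
    labels: Sequence[str] | None = None,
) -> tuple[dict[str, GenotypeTable], dict]:
    """Populations diverged from shared ancestral frequencies at target Fst.

    Per population and locus, frequencies are drawn from the Balding-
    Nichols distribution (Dirichlet with parameters p_i (1 - F) / F), then
    genotypes are simulated under HWE (``ploidy=2``) or as haploid calls
    (``ploidy=1``, Y-style single-copy loci).  Allele labels are integer CE
    designations, so tables feed the repeat-count (Rst) view directly.
    """
    if not 0.0 < f_div < 1.0:
        raise ValueError("F_div must be in (0, 1)")
    rng = _rng(seed)
    if labels is None:
        labels = [f"POP{i + 1}" for i in range(n_pops)]
    panel: Panel = {}
    for name in ancestral_freqs:
        if len(ancestral_freqs[name]) < 2:
            raise ValueError(f"degenerate ancestral vector at {name!r}")
        panel[name] = MarkerDef(name, "autosomal" if ploidy == 2 else "y_single", 4)
    scale = (1.0 - f_div) / f_div
    truth: dict = {"f_div": f_div, "pop_freqs": {}}
    tables: dict[str, GenotypeTable] = {}
    for pop in labels:
        samples = [f"{pop}_S{i + 1:04d}" for i in range(n_per_pop)]
        diploid: dict[str, dict[str, tuple[str, str]]] = {}
        haploid: dict[str, dict[str, tuple[str, ...]]] = {}
        pop_freqs: dict[str, dict[str, float]] = {}
        for marker, fmap in ancestral_freqs.items():
            alleles = list(fmap.keys())
            alpha = np.asarray(list(fmap.values()), dtype=float) * scale
            p = rng.dirichlet(alpha)
            p = np.clip(p, 1e-12, None)
            p = p / p.sum()
            pop_freqs[marker] = dict(zip(alleles, p.tolist()))
            if ploidy == 2:
                draws = rng.choice(len(alleles), size=(n_per_pop, 2), p=p)
                diploid[marker] = {
                    s: (alleles[i], alleles[j])
                    for s, (i, j) in zip(samples, draws)
                }
            else:
                draws = rng.choice(len(alleles), size=n_per_pop, p=p)
                haploid[marker] = {s: (alleles[i],) for s, i in zip(samples, draws)}
        sex = {s: "M" for s in samples} if ploidy == 1 else {}
        tables[pop] = GenotypeTable(dict(panel), samples, sex, diploid, haploid)
        truth["pop_freqs"][pop] = pop_freqs
    return tables, truth


def generate_dataset(config: SimConfig | None = None) -> tuple[GenotypeTable, dict]:
    """Full synthetic study table: autosomal for all, Y for males only.

    Returns the sequence-level genotype table and a truth sidecar holding
    the generating frequencies and parameters.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    panel = config.panel or default_panel()
    config = replace(config, panel=panel)
    freqs = build_panel_frequencies(config, rng)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    sex = {
        s: ("M" if i < config.n_males else "F") for i, s in enumerate(samples)
    }
    diploid: dict[str, dict[str, tuple[str, str]]] = {}
    for marker, mdef in panel.items():
        if mdef.ploidy_class != "autosomal":
            continue
        pairs = simulate_autosomal_genotypes(freqs[marker], n, config.inbreeding_f, rng)
        diploid[marker] = dict(zip(samples, pairs))
    y_freqs = {m: freqs[m] for m, d in panel.items() if d.is_y}
    males = [s for s in samples if sex[s] == "M"]
    haploid: dict[str, dict[str, tuple[str, ...]]] = {}
    if males:
        raw = simulate_y_haplotypes(
            y_freqs,
            len(males),
            rng,
            panel,
            config.n_founders,
            config.y_mutation_rate,
        )
        for marker, calls in raw.items():
            haploid[marker] = {
                males[i]: alleles
                for i, (_, alleles) in enumerate(sorted(calls.items()))
            }
    table = GenotypeTable.from_calls(panel, samples, sex, diploid, haploid)
    truth = {
        "seed": config.seed,
        "inbreeding_f": config.inbreeding_f,
        "n_samples": n,
        "n_males": config.n_males,
        "frequencies": freqs,
    }
    return table, truth
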