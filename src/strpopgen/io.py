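"""File formats, run configuration and the end-to-end pipeline.

Canonical interchange formats (all plain text):

* genotype CSV — wide; ``sample`` index column, optional ``sex`` column,
  two columns ``M.1``/``M.2`` per autosomal marker, one column per Y marker
  with comma-joined labels for multi-copy loci; empty cell = missing.
* panel CSV — ``name,class,period`` with class in
  {autosomal, y_single, y_multicopy}.
* kit CSV — ``kit,locus`` long format.
* frequency CSV — ``marker,allele,frequency,gene_count`` at 6 decimals.
* distance matrices — square CSV and PHYLIP distance format.

Every pipeline run writes a machine-readable manifest (inputs, seed,
package version, parameters, output checksums) alongside its outputs, and
two runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .autosomal import (
    FrequencyTable,
    combined_powers,
    forensic_params,
    hwe_test_table,
)
from .distance import DistanceMatrix, pairwise_fst, pairwise_rst
from .nomenclature import MarkerDef, allele_inventory
from .simulate import SimConfig, generate_dataset, simulate_diverged_populations
from .structure import classical_mds, neighbor_joining, to_newick
from .tables import GenotypeTable, Panel
from .yhaplotype import KitDef, build_haplotypes, haplotype_stats, kit_comparison

__all__ = [
    "read_panel",
    "write_panel",
    "read_genotype_table",
    "write_genotype_table",
    "read_kit_definitions",
    "write_frequency_table",
    "write_distance_csv",
    "write_distance_phylip",
    "RunConfig",
    "pipeline_run",
]

log = logging.getLogger("strpopgen")


def read_panel(path: str | Path) -> Panel:
    df = pd.read_csv(path)
    panel: Panel = {}
    for _, row in df.iterrows():
        panel[str(row["name"])] = MarkerDef(
            str(row["name"]), str(row["class"]), int(row["period"])
        )
    return panel


def write_panel(panel: Panel, path: str | Path) -> None:
    pd.DataFrame(
        [(m.name, m.ploidy_class, m.period) for m in panel.values()],
        columns=["name", "class", "period"],
    ).to_csv(path, index=False)


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_genotype_table(path: str | Path, panel: Panel) -> GenotypeTable:
    """Read the wide genotype CSV/TSV; errors carry 1-based line numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, index_col=0)
    try:
        return GenotypeTable.from_frame(df, panel)
    except ValueError as exc:
        # re-raise with the offending sample's line number when possible
        msg = str(exc)
        for lineno, sample in enumerate(df.index, start=2):
            if str(sample) in msg:
                raise ValueError(f"{path}:{lineno}: {msg}") from exc
        raise ValueError(f"{path}: {msg}") from exc


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep(path))


def read_kit_definitions(path: str | Path) -> list[KitDef]:
    df = pd.read_csv(path)
    kits = []
    for name, group in df.groupby("kit", sort=True):
        kits.append(KitDef(str(name), tuple(group["locus"].astype(str))))
    return kits


def write_frequency_table(ft: FrequencyTable, path: str | Path) -> None:
    df = ft.to_frame()
    df["frequency"] = df["frequency"].map(lambda x: f"{x:.6f}")
    df.to_csv(path, index=False)


def write_distance_csv(matrix: DistanceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, float_format="%.6f")


def write_distance_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    lines = [f"{len(matrix.labels)}"]
    for i, lab in enumerate(matrix.labels):
        row = " ".join(f"{v:.6f}" for v in matrix.values[i])
        lines.append(f"{lab[:10]:<10s} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    out_dir: str | Path = "strpopgen_out"
    input_path: str | Path | None = None
    panel_path: str | Path | None = None
    kits_path: str | Path | None = None
    levels: tuple[str, ...] = ("length", "sequence")
    alpha: float = 0.05
    hwe_permutations: int = 17000
    seed: int = 0
    n_samples: int = 628
    n_males: int = 547
    n_populations: int = 4
    f_div: float = 0.05
    distance_loci: int = 15
    distance_n: int = 200
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def pipeline_run(config: RunConfig) -> dict:
    """Run simulate/read -> freqs -> params+HWE -> yhap -> dist -> MDS/NJ.

    Stage failures are logged per stage and downstream dependents are
    skipped; the returned manifest records what ran, with what inputs, and
    the checksum of every output.  Identical config (including seed) gives
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    manifest: dict = {
        "package": "strpopgen",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
        "outputs": {},
    }
    failed: set[str] = set()

    def record(name: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    def stage(name: str, deps: Sequence[str] = ()):  # tiny decorator
        def wrap(fn):
            if any(d in failed for d in deps):
                log.warning("stage %s skipped (failed deps)", name)
                manifest["stages"][name] = "skipped"
                return None
            try:
                result = fn()
                manifest["stages"][name] = "ok"
                return result
            except Exception as exc:  # noqa: BLE001 - isolate per stage
                log.error("stage %s failed: %s", name, exc)
                manifest["stages"][name] = f"failed: {exc}"
                failed.add(name)
                return None

        return wrap

    # -- input / simulate -------------------------------------------------
    @stage("input")
    def table():
        if config.input_path is not None:
            if config.panel_path is None:
                raise ValueError("panel_path required with input_path")
            panel = read_panel(config.panel_path)
            t = read_genotype_table(config.input_path, panel)
            if not t.samples:
                raise ValueError("empty input table")
            return t
        sim = SimConfig(
            n_samples=config.n_samples, n_males=config.n_males, seed=config.seed
        )
        t, truth = generate_dataset(sim)
        write_genotype_table(t, out / "genotypes.csv")
        record("input", out / "genotypes.csv")
        _json_dump(
            {
                "seed": truth["seed"],
                "inbreeding_f": truth["inbreeding_f"],
                "n_samples": truth["n_samples"],
                "n_males": truth["n_males"],
                "frequencies": truth["frequencies"],
            },
            out / "truth.json",
        )
        record("input", out / "truth.json")
        return t

    if table is None:
        _json_dump(manifest, out / "manifest.json")
        raise RuntimeError("input stage failed; see manifest")

    # -- frequencies & inventory ------------------------------------------
    typed_markers = [m for m in table.markers() if table.n_typed(m) > 0]

    @stage("freqs", deps=["input"])
    def _freqs():
        for level in config.levels:
            ft = FrequencyTable.from_table(table, level, typed_markers)
            p = out / f"frequencies_{level}.csv"
            write_frequency_table(ft, p)
            record("freqs", p)
        inv = {
            level: allele_inventory(table, level).totals for level in config.levels
        }
        _json_dump(inv, out / "allele_inventory.json")
        record("freqs", out / "allele_inventory.json")

    # -- autosomal parameters + HWE ---------------------------------------
    @stage("params", deps=["input"])
    def _params():
        summary = {}
        for level in config.levels:
            df = forensic_params(table, level)
            p = out / f"forensic_params_{level}.csv"
            df.to_csv(p, index=False, float_format="%.6f")
            record("params", p)
            cp = combined_powers(df)
            summary[level] = {
                "CPE": cp.cpe_repr,
                "CPD": cp.cpd_repr,
                "n_loci": cp.n_loci,
            }
            hwe = hwe_test_table(
                table,
                level,
                alpha=config.alpha,
                n_permutations=config.hwe_permutations,
                seed=config.seed,
            )
            hp = out / f"hwe_{level}.csv"
            hwe.to_csv(hp, index=False, float_format="%.6f")
            record("params", hp)
        _json_dump(summary, out / "combined_powers.json")
        record("params", out / "combined_powers.json")

    # -- Y haplotypes ------------------------------------------------------
    @stage("yhap", deps=["input"])
    def _yhap():
        if not table.males:
            raise ValueError("no male samples: Y-haplotype stage needs males")
        stats = {}
        for level in config.levels:
            haps, excluded = build_haplotypes(table, None, level)
            st = haplotype_stats(haps, level)
            stats[level] = {**dataclasses.asdict(st), "n_excluded": excluded}
        _json_dump(stats, out / "haplotype_stats.json")
        record("yhap", out / "haplotype_stats.json")
        if config.kits_path is not None:
            kits = read_kit_definitions(config.kits_path)
            for level in config.levels:
                df = kit_comparison(table, kits, level)
                p = out / f"kit_comparison_{level}.csv"
                df.to_csv(p, index=False, float_format="%.8f")
                record("yhap", p)

    # -- population structure ---------------------------------------------
    @stage("dist", deps=["input"])
    def matrices():
        if config.n_populations < 2:
            raise ValueError("distance stage needs >= 2 populations")
        ft = FrequencyTable.from_table(table, "length", typed_markers)
        auto = [m for m in table.markers("autosomal") if m in ft.freqs][
            : config.distance_loci
        ]
        anc_auto = {m: ft.freqs[m] for m in auto if len(ft.freqs[m]) >= 2}
        pops_auto, _ = simulate_diverged_populations(
            anc_auto,
            config.f_div,
            config.distance_n,
            config.n_populations,
            ploidy=2,
            seed=config.seed + 1,
        )
        fst = pairwise_fst(pops_auto)
        y = [m for m in table.markers("y_single") if m in ft.freqs][
            : config.distance_loci
        ]
        anc_y = {m: ft.freqs[m] for m in y if len(ft.freqs[m]) >= 2}
        if not anc_y:
            raise ValueError("no polymorphic Y loci for the Rst matrix")
        pops_y, _ = simulate_diverged_populations(
            anc_y,
            config.f_div,
            config.distance_n,
            config.n_populations,
            ploidy=1,
            seed=config.seed + 2,
        )
        rst = pairwise_rst(pops_y)
        for name, m in (("fst", fst), ("rst", rst)):
            write_distance_csv(m, out / f"{name}_matrix.csv")
            record("dist", out / f"{name}_matrix.csv")
            write_distance_phylip(m, out / f"{name}_matrix.phy")
            record("dist", out / f"{name}_matrix.phy")
        return fst, rst

    @stage("mds", deps=["dist"])
    def _mds():
        fst, rst = matrices
        for name, m in (("fst", fst), ("rst", rst)):
            res = classical_mds(m, dims=2)
            p = out / f"mds_{name}.csv"
            res.to_frame().to_csv(p, float_format="%.6f")
            record("mds", p)

    @stage("njtree", deps=["dist"])
    def _nj():
        fst, rst = matrices
        for name, m in (("fst", fst), ("rst", rst)):
            if len(m.labels) < 3:
                continue
            tree = neighbor_joining(m)
            p = out / f"nj_{name}.nwk"
            p.write_text(to_newick(tree) + "\n")
            record("njtree", p)

    _json_dump(manifest, out / "manifest.json")
    return manifest
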