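"""TSV / GMT readers and writers.

All tables are tab-separated with a header row.  Files written by the
pipeline carry a single leading comment line ``# stage=<name>
config_hash=<hash>`` declaring their producing stage; readers skip
``#``-comment lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError
from .overlap import GeneSet
from .synthetic import ExpressionExperiment


def write_tsv(df: pd.DataFrame, path, stage: str | None = None,
              config_hash: str | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage is not None:
            fh.write(f"# stage={stage} config_hash={config_hash or 'na'}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_gene_set(gs: GeneSet, path, stage: str | None = None, config_hash: str | None = None) -> None:
    """One-symbol-per-line TSV with header ``symbol, direction, species``."""
    rows = [
        {
            "symbol": s,
            "direction": (gs.directions or {}).get(s, ""),
            "species": gs.species,
        }
        for s in sorted(gs.symbols)
    ]
    write_tsv(pd.DataFrame(rows, columns=["symbol", "direction", "species"]), path,
              stage=stage, config_hash=config_hash)


def read_gene_set(path, study_id: str | None = None) -> GeneSet:
    df = read_tsv(path, dtype=str)
    if "symbol" not in df.columns:
        raise ConfigurationError(f"{path}: gene list must have a 'symbol' column")
    df = df.dropna(subset=["symbol"])
    species = "unknown"
    if "species" in df.columns and df["species"].notna().any():
        species = str(df["species"].dropna().iloc[0])
    directions = None
    if "direction" in df.columns and df["direction"].notna().any():
        directions = {
            r.symbol: r.direction for r in df.itertuples() if isinstance(r.direction, str) and r.direction
        }
    return GeneSet(
        study_id=study_id or Path(path).stem,
        symbols=frozenset(df["symbol"]),
        species=species,
        directions=directions,
    )


def write_experiment(exp: ExpressionExperiment, out_dir, truth: pd.DataFrame | None = None,
                     stage: str = "simulate", config_hash: str | None = None) -> dict[str, Path]:
    """Write matrix / sample sheet / probe map (/ detection / truth) TSVs."""
    out_dir = Path(out_dir)
    paths = {
        "expression": out_dir / "expression.tsv",
        "samples": out_dir / "samples.tsv",
        "probe_map": out_dir / "probe_map.tsv",
    }
    write_tsv(exp.matrix, paths["expression"], stage, config_hash, index=True)
    write_tsv(exp.samples.reset_index(), paths["samples"], stage, config_hash)
    write_tsv(exp.probe_map.reset_index(), paths["probe_map"], stage, config_hash)
    if exp.detection is not None:
        paths["detection"] = out_dir / "detection.tsv"
        write_tsv(exp.detection, paths["detection"], stage, config_hash, index=True)
    if truth is not None:
        paths["truth"] = out_dir / "truth.tsv"
        write_tsv(truth, paths["truth"], stage, config_hash)
    return paths


def read_experiment(in_dir) -> ExpressionExperiment:
    in_dir = Path(in_dir)
    matrix = read_tsv(in_dir / "expression.tsv", index_col="probe_id")
    samples = read_tsv(in_dir / "samples.tsv", index_col="sample_id")
    probe_map = read_tsv(in_dir / "probe_map.tsv", index_col="probe_id")["gene_symbol"]
    detection = None
    det_path = in_dir / "detection.tsv"
    if det_path.exists():
        detection = read_tsv(det_path, index_col="probe_id")
    exp = ExpressionExperiment(matrix=matrix, samples=samples, probe_map=probe_map,
                               detection=detection)
    exp.validate()
    return exp


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column ``from<TAB>to`` symbol translation table."""
    df = read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: ortholog map needs two columns (from, to)")
    return dict(df.iloc[:, :2].dropna().itertuples(index=False))


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Standard GMT: ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``."""
    catalog: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(f"{path}:{line_no}: GMT line needs id, description, >=1 gene")
            pid, desc, genes = fields[0], fields[1], fields[2:]
            catalog[pid] = (desc, frozenset(g.upper() for g in genes if g))
    return catalog


def write_gmt(catalog: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for pid in sorted(catalog):
            name, members = catalog[pid]
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")
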