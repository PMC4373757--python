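"""End-to-end pipeline: simulate -> DE -> concordance -> network -> enrichment.

Configuration lives in :class:`PipelineConfig` (YAML round-trippable);
:func:`run_pipeline` executes the stages, writes every output as TSV with a
stage/config-hash header line, and emits a run manifest.  All randomness
flows from the single config seed via named per-stage substreams, so a
fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, de, enrichment, io, network, overlap, synthetic
from .errors import PipelineStageError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "stage_seed_int"]


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Named substream: one root seed, decorrelated streams per stage."""
    return np.random.SeedSequence([seed, zlib.crc32(stage.encode())])


def stage_seed_int(seed: int, stage: str) -> int:
    """Plain-integer form of the named substream (for seed-typed configs)."""
    return int(stage_seed(seed, stage).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All thresholds and paths of the pipeline.

    Defaults are the printed constants of the analysis this pipeline
    mirrors: BH significance at 0.05, volcano highlight thresholds 2.8/0.35
    at 2 weeks and 1.5/0.5 at 4 weeks, hub criterion of 10 edges, a
    10,000-gene pool with 10,000 occurrence-null replicates, and an
    at-least-5-studies recurrence level.
    """

    seed: int = 0
    out_dir: str = "results/pipeline"
    # inputs; None => synthesise with the synthetic_data module
    experiment_dir: str | None = None
    study_lists: list[str] = field(default_factory=list)
    edge_table: str | None = None
    gmt: str | None = None
    ortholog_map: str | None = None
    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "de", "overlap", "occurrence", "network", "enrich"]
    )
    # thresholds
    alpha: float = 0.05
    alpha_det: float = 0.05
    min_fraction: float = 0.5
    volcano_up: dict = field(default_factory=lambda: {"2w": 2.8, "4w": 1.5, "8w": 1.5})
    volcano_down: dict = field(default_factory=lambda: {"2w": 0.35, "4w": 0.5, "8w": 0.5})
    min_degree: int = 10
    min_score: float | None = None
    universe: int = 10_000
    n_sims: int = 10_000
    m_level: int = 5
    # synthetic generation knobs
    sim: dict = field(default_factory=dict)
    study_sim: dict = field(default_factory=dict)

    def __post_init__(self):
        # canonicalise to YAML-native containers so configs round-trip losslessly
        def listify(v):
            if isinstance(v, tuple):
                return [listify(x) for x in v]
            if isinstance(v, dict):
                return {k: listify(x) for k, x in v.items()}
            return v

        self.sim = listify(dict(self.sim))
        self.study_sim = listify(dict(self.study_sim))
        self.study_lists = list(self.study_lists)
        self.stages = list(self.stages)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineStageError("config", "unknown-field", f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # hash the analysis parameters only; the destination directory does
        # not change what is computed
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        canon = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _fail(stage: str, code: str, msg: str):
    raise PipelineStageError(stage, code, msg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    manifest: dict = {
        "ptoa_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config_hash": h,
        "stages": {},
    }

    exp = truth = None
    de_results: dict[str, de.DEResult] = {}
    timepoints: tuple[str, ...] = ()

    # --- simulate -----------------------------------------------------------
    if "simulate" in cfg.stages:
        stage = "simulate"
        try:
            sim_cfg = synthetic.SimConfig(**{"seed": stage_seed_int(cfg.seed, stage), **cfg.sim})
            exp, truth = synthetic.simulate_experiment(sim_cfg)
            io.write_experiment(exp, out / "experiment", truth=truth, stage=stage, config_hash=h)
            manifest["stages"][stage] = {
                "n_probes": int(exp.matrix.shape[0]),
                "n_samples": int(exp.matrix.shape[1]),
            }
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001 - stage boundary
            _fail(stage, "simulate-failed", str(e))
    elif cfg.experiment_dir is not None:
        exp = io.read_experiment(cfg.experiment_dir)

    # --- differential expression -------------------------------------------
    if "de" in cfg.stages:
        stage = "de"
        if exp is None:
            _fail(stage, "missing-input", "no experiment: enable the simulate stage or set experiment_dir")
        timepoints = tuple(dict.fromkeys(exp.samples["timepoint"]))
        try:
            counts = {}
            for tp in timepoints:
                res = de.paired_de(exp, tp, alpha=cfg.alpha, alpha_det=cfg.alpha_det,
                                   min_fraction=cfg.min_fraction)
                de_results[tp] = res
                table = res.genes.reset_index()
                table["volcano"] = de.volcano_classify(
                    res, up_fc=cfg.volcano_up.get(tp, 2.0), down_fc=cfg.volcano_down.get(tp, 0.5)
                ).values
                io.write_tsv(table, out / f"de_{tp}.tsv", stage, h)
                if res.significant_genes:
                    io.write_gene_set(res.gene_set(f"this_study_{tp}"), out / f"genelist_{tp}.tsv", stage, h)
                else:  # nothing significant: emit an empty list, keep the file contract
                    io.write_tsv(pd.DataFrame(columns=["symbol", "direction", "species"]),
                                 out / f"genelist_{tp}.tsv", stage, h)
                counts[tp] = int(res.genes["significant"].sum())
            manifest["stages"][stage] = {"significant_genes": counts}
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            _fail(stage, "de-failed", str(e))

    # --- cross-study gene lists --------------------------------------------
    study_sets: list[overlap.GeneSet] = []
    need_lists = {"overlap", "occurrence"} & set(cfg.stages)
    if need_lists:
        stage = "overlap"
        try:
            if cfg.study_lists:
                study_sets = [io.read_gene_set(p) for p in cfg.study_lists]
            else:
                study_cfg = synthetic.StudySimConfig(
                    **{"seed": stage_seed_int(cfg.seed, "study_sim"), "universe_size": cfg.universe, **cfg.study_sim}
                )
                study_sets = synthetic.simulate_study_collection(study_cfg)
            omap = io.read_ortholog_map(cfg.ortholog_map) if cfg.ortholog_map else None
            study_sets = overlap.harmonize_symbols(study_sets, omap)
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            _fail(stage, "lists-failed", str(e))

    if "overlap" in cfg.stages:
        stage = "overlap"
        try:
            rows = []
            for i in range(len(study_sets)):
                for j in range(i + 1, len(study_sets)):
                    a, b = study_sets[i], study_sets[j]
                    k = len(a.symbols & b.symbols)
                    res = overlap.hypergeom_overlap(k, a.size, b.size, cfg.universe)
                    rows.append({"study1": a.study_id, "study2": b.study_id, "k": k,
                                 "n1": a.size, "n2": b.size, "U": cfg.universe,
                                 "pmf": res.pmf, "p_upper": res.p_upper})
            pairwise = pd.DataFrame(rows)
            io.write_tsv(pairwise, out / "pairwise_overlap.tsv", stage, h)
            if 2 <= len(study_sets[:3]) <= 4:
                regions = overlap.venn_regions(study_sets[:3])
                io.write_tsv(overlap.venn_table(regions), out / "venn_regions.tsv", stage, h)
            manifest["stages"][stage] = {"n_pairs": len(rows)}
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            _fail(stage, "overlap-failed", str(e))

    if "occurrence" in cfg.stages:
        stage = "occurrence"
        try:
            prof = overlap.occurrence_histogram(study_sets, U=cfg.universe)
            null = overlap.occurrence_null(
                [gs.size for gs in study_sets], cfg.universe, cfg.n_sims,
                seed=stage_seed(cfg.seed, stage),
            )
            prof.expected, prof.expected_ge = null.expected, null.expected_ge
            prof.sim_sd, prof.sim_sd_ge = null.sim_sd, null.sim_sd_ge
            prof.n_sims = null.n_sims
            closed = overlap.occurrence_expectation([gs.size for gs in study_sets], cfg.universe)
            frame = prof.to_frame()
            frame["expected_closed_form"] = closed
            io.write_tsv(frame, out / "occurrence.tsv", stage, h)
            recurrent = sorted(prof.members_at_least(cfg.m_level))
            io.write_tsv(pd.DataFrame({"symbol": recurrent}), out / f"recurrent_ge{cfg.m_level}.tsv", stage, h)
            manifest["stages"][stage] = {
                "observed_ge_m": float(prof.observed_ge[cfg.m_level]),
                "expected_ge_m": float(prof.expected_ge[cfg.m_level]),
            }
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            _fail(stage, "occurrence-failed", str(e))

    # --- network ------------------------------------------------------------
    if "network" in cfg.stages:
        stage = "network"
        try:
            first_tp = timepoints[0] if timepoints else None
            if first_tp is None or first_tp not in de_results:
                _fail(stage, "missing-input", "network stage needs DE results (enable the de stage)")
            de_res = de_results[first_tp]
            if cfg.edge_table:
                if not Path(cfg.edge_table).exists():
                    _fail(stage, "missing-input", f"edge table not found: {cfg.edge_table}")
                edges = io.read_tsv(cfg.edge_table)
            else:
                sig = sorted(de_res.significant_genes)
                if not sig:
                    edges = pd.DataFrame(columns=["protein1", "protein2", "combined_score"])
                else:
                    edges = synthetic.simulate_edge_table(
                        sig, seed=stage_seed_int(cfg.seed, "edge_sim")
                    )
            net = network.build_network(de_res, edges, min_score=cfg.min_score)
            hubs = network.find_hubs(net, min_degree=cfg.min_degree)
            io.write_tsv(net.node_table(), out / "network_nodes.tsv", stage, h)
            io.write_tsv(net.edge_table(), out / "network_edges.tsv", stage, h)
            io.write_tsv(hubs, out / "hubs.tsv", stage, h)
            net.write_graphml(out / "network.graphml")
            manifest["stages"][stage] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                                         "n_hubs": int(len(hubs))}
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            _fail(stage, "network-failed", str(e))

    # --- enrichment ---------------------------------------------------------
    if "enrich" in cfg.stages:
        stage = "enrich"
        try:
            first_tp = timepoints[0] if timepoints else None
            if first_tp is None or first_tp not in de_results:
                _fail(stage, "missing-input", "enrich stage needs DE results (enable the de stage)")
            de_res = de_results[first_tp]
            detected = de_res.genes.index[de_res.genes["detected"]]
            if cfg.gmt:
                if not Path(cfg.gmt).exists():
                    _fail(stage, "missing-input", f"GMT catalogue not found: {cfg.gmt}")
                catalog = io.read_gmt(cfg.gmt)
            else:
                sig = sorted(de_res.significant_genes)
                catalog = synthetic.simulate_gmt(
                    list(detected),
                    planted={"PW_PLANTED": sig[: min(40, len(sig))]} if sig else None,
                    seed=stage_seed_int(cfg.seed, "gmt_sim"),
                )
            result = enrichment.enrich(de_res.significant_genes, catalog, detected)
            io.write_tsv(result, out / "enrichment.tsv", stage, h)
            manifest["stages"][stage] = {
                "n_pathways_tested": int(len(result)),
                "n_significant": int(len(enrichment.significant_pathways(result, cfg.alpha))),
            }
        except PipelineStageError:
            raise
        except Exception as e:  # noqa: BLE001
            _fail(stage, "enrich-failed", str(e))

    cfg.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
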