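"""Synthetic data generators for the whole pipeline.

Everything downstream (paired DE, concordance statistics, network and
enrichment analysis) runs against data produced here, so no external
download is ever required.  Two main generators are provided:

* :func:`simulate_experiment` — a paired two-limb microarray experiment:
  eight animals per timepoint, each contributing an operated (ipsilateral)
  and an unoperated control (contralateral) limb sample, with a planted
  differential-expression signal that decays over the post-surgery time
  course (by default 1224 -> 76 -> 2 regulated genes at 2, 4 and 8 weeks).
* :func:`simulate_study_collection` — a collection of study gene lists over
  a common universe with a planted core of recurrently regulated genes,
  the fixture for multi-study occurrence analysis.

Secondary helpers build protein-interaction edge tables with planted hubs
and toy GMT pathway catalogues.  All generators are driven by a single RNG
seeded from their config, so identical seeds give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .overlap import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "StudySimConfig",
    "ExpressionExperiment",
    "simulate_experiment",
    "simulate_study_collection",
    "simulate_edge_table",
    "simulate_gmt",
    "gene_names",
]

#: paper-scale study list sizes: the index study (1224 significant genes at
#: 2 weeks) plus eight comparison arrays; with U = 10,000 the analytic
#: expectation of genes shared by >= 5 lists under the random null is 0.74.
DEFAULT_STUDY_SIZES = (1224, 200, 300, 400, 500, 600, 700, 800, 900)


def gene_names(n: int, prefix: str = "g") -> list[str]:
    """Synthetic gene symbols g000001..gN."""
    return [f"{prefix}{i + 1:06d}" for i in range(n)]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the paired expression simulator.

    The defaults emulate the study design this pipeline targets: three
    timepoints with eight animal pairs each, a DE signal of 1224/76/2 genes
    decaying over time, absolute planted effects between log2FC 0.585
    (fold change 1.5) and 3.0, and residual noise of 0.5 on the log2 scale.
    """

    n_genes: int = 10_000
    n_probes: int = 12_000  # ~1.2 probes per gene, as on whole-genome chips
    n_pairs: int = 8
    timepoints: tuple[str, ...] = ("2w", "4w", "8w")
    de_counts: tuple[int, ...] = (1224, 76, 2)
    log2fc_range: tuple[float, float] = (0.585, 3.0)
    noise_sd: float = 0.5
    frac_up: float = 0.6
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    animal_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < self.n_genes:
            raise ConfigurationError(f"n_probes ({self.n_probes}) must be >= n_genes ({self.n_genes})")
        if self.n_pairs < 1:
            raise ConfigurationError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if len(self.de_counts) != len(self.timepoints):
            raise ConfigurationError("de_counts must have one entry per timepoint")
        for tp, c in zip(self.timepoints, self.de_counts):
            if not 0 <= c <= self.n_genes:
                raise ConfigurationError(f"de_counts[{tp}] = {c} outside [0, n_genes={self.n_genes}]")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.log2fc_range
        if not 0 < lo <= hi:
            raise ConfigurationError(f"log2fc_range must satisfy 0 < lo <= hi, got {self.log2fc_range}")
        if not 0 <= self.frac_up <= 1:
            raise ConfigurationError(f"frac_up must be in [0, 1], got {self.frac_up}")


@dataclass(frozen=True)
class StudySimConfig:
    """Configuration of the multi-study gene-list simulator."""

    n_studies: int = 9
    universe_size: int = 10_000
    set_sizes: tuple[int, ...] = DEFAULT_STUDY_SIZES
    planted_core: int = 22
    m_core: int = 5
    seed: int = 0

    def validate(self) -> None:
        if len(self.set_sizes) != self.n_studies:
            raise ConfigurationError(
                f"set_sizes has {len(self.set_sizes)} entries for n_studies={self.n_studies}"
            )
        for i, n in enumerate(self.set_sizes):
            if not 0 < n <= self.universe_size:
                raise ConfigurationError(
                    f"set_sizes[{i}] = {n} outside (0, universe_size={self.universe_size}]"
                )
        if not 0 < self.m_core <= self.n_studies:
            raise ConfigurationError(f"m_core must be in (0, n_studies], got {self.m_core}")
        if self.planted_core < 0:
            raise ConfigurationError(f"planted_core must be >= 0, got {self.planted_core}")
        # the m_core-th largest list caps how many core genes can be planted
        cap = sorted(self.set_sizes, reverse=True)[self.m_core - 1]
        if self.planted_core > cap:
            raise ConfigurationError(
                f"planted_core = {self.planted_core} infeasible: the {self.m_core} largest "
                f"lists can each hold at most {cap} core genes"
            )


@dataclass
class ExpressionExperiment:
    """A paired probe-level expression experiment.

    ``matrix`` holds log2 intensities (probes x samples); ``samples`` maps
    sample id to (animal_id, limb, timepoint); ``probe_map`` maps probe id
    to gene symbol; ``detection`` optionally holds probe x sample detection
    p-values.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    probe_map: pd.Series
    detection: pd.DataFrame | None = None

    def validate(self) -> None:
        missing = set(self.matrix.index) - set(self.probe_map.index)
        if missing:
            raise ConfigurationError(f"{len(missing)} probes in matrix missing from probe_map")
        for (tp, animal), grp in self.samples.groupby(["timepoint", "animal_id"]):
            limbs = sorted(grp["limb"])
            if limbs != ["contra", "ipsi"]:
                raise ConfigurationError(
                    f"animal {animal} at {tp} must contribute exactly one ipsi and one "
                    f"contra sample, got {limbs}"
                )

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        return self.samples[self.samples["timepoint"] == timepoint]


def simulate_experiment(cfg: SimConfig) -> tuple[ExpressionExperiment, pd.DataFrame]:
    """Simulate a paired limb experiment with a planted decaying DE signal.

    Returns the experiment plus the ground truth: one row per (gene,
    timepoint) with the planted signed log2 fold change (0 for unregulated
    genes).  Model per probe p of gene g, animal a, limb l:

        y = mu_g + delta_p + alpha_{a,g} + s_l * beta_{g,t} + eps

    where ``mu_g ~ N(baseline_mean, baseline_sd)`` is the gene baseline,
    ``delta_p`` a fixed probe offset, ``alpha`` an animal-by-gene random
    effect shared by both limbs (it cancels in the within-animal pairing),
    ``beta`` the planted effect applied to ipsilateral samples only
    (``s_l`` is 1 for ipsi, 0 for contra), and ``eps ~ N(0, noise_sd)``
    independent per probe and sample.  Later timepoints' regulated genes
    are nested inside earlier ones, mirroring the persistence of a few
    genes across the whole time course.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    probes = [f"p{i + 1:06d}" for i in range(cfg.n_probes)]

    # probe -> gene: every gene gets one probe; extra probes land on random genes
    gene_idx_of_probe = np.concatenate([
        np.arange(cfg.n_genes),
        rng.integers(0, cfg.n_genes, size=cfg.n_probes - cfg.n_genes),
    ])
    probe_map = pd.Series([genes[i] for i in gene_idx_of_probe], index=pd.Index(probes, name="probe_id"),
                          name="gene_symbol")

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    probe_offset = rng.normal(0.0, 0.25, size=cfg.n_probes)

    # planted DE genes, nested over the time course (signal decays)
    lo, hi = cfg.log2fc_range
    order = np.argsort(cfg.de_counts)[::-1]  # largest first
    de_sets: dict[str, np.ndarray] = {}
    prev: np.ndarray | None = None
    for pos in order:
        tp, count = cfg.timepoints[pos], cfg.de_counts[pos]
        pool = prev if prev is not None and count <= len(prev) else np.arange(cfg.n_genes)
        chosen = rng.choice(pool, size=count, replace=False) if count else np.array([], dtype=int)
        de_sets[tp] = np.sort(chosen)
        prev = de_sets[tp]
    beta = np.zeros((cfg.n_genes, len(cfg.timepoints)))
    for t, tp in enumerate(cfg.timepoints):
        idx = de_sets[tp]
        if len(idx) == 0:
            continue
        mag = rng.uniform(lo, hi, size=len(idx))
        sign = np.where(rng.random(len(idx)) < cfg.frac_up, 1.0, -1.0)
        beta[idx, t] = mag * sign

    sample_rows = []
    columns: dict[str, np.ndarray] = {}
    probe_mu = mu[gene_idx_of_probe] + probe_offset
    for t, tp in enumerate(cfg.timepoints):
        probe_beta = beta[gene_idx_of_probe, t]
        for a in range(cfg.n_pairs):
            animal = f"{tp}_m{a + 1:02d}"
            alpha = rng.normal(0.0, cfg.animal_sd, size=cfg.n_genes)[gene_idx_of_probe]
            for limb in ("ipsi", "contra"):
                sid = f"{animal}_{limb}"
                shift = probe_beta if limb == "ipsi" else 0.0
                eps = rng.normal(0.0, cfg.noise_sd, size=cfg.n_probes) if cfg.noise_sd > 0 else 0.0
                columns[sid] = probe_mu + alpha + shift + eps
                sample_rows.append({"sample_id": sid, "animal_id": animal,
                                    "limb": limb, "timepoint": tp})

    matrix = pd.DataFrame(columns, index=pd.Index(probes, name="probe_id"))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = pd.DataFrame(
        beta, index=pd.Index(genes, name="gene"), columns=list(cfg.timepoints)
    ).reset_index().melt(id_vars="gene", var_name="timepoint", value_name="log2fc_true")
    truth["is_de"] = truth["log2fc_true"] != 0.0

    exp = ExpressionExperiment(matrix=matrix, samples=samples, probe_map=probe_map)
    exp.validate()
    return exp, truth


def simulate_study_collection(cfg: StudySimConfig) -> list[GeneSet]:
    """Simulate study gene lists with a planted recurrently-regulated core.

    Each of the ``planted_core`` core genes is inserted into exactly
    ``m_core`` randomly chosen studies; remaining slots are filled by
    sampling without replacement from the universe (background genes may by
    chance raise a core gene's occurrence further).  Every list has exactly
    its configured size and no duplicates.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    universe = np.array(gene_names(cfg.universe_size))

    core_idx = rng.choice(cfg.universe_size, size=cfg.planted_core, replace=False)
    membership: list[set[int]] = [set() for _ in range(cfg.n_studies)]
    for g in core_idx:
        for s in rng.choice(cfg.n_studies, size=cfg.m_core, replace=False):
            membership[s].add(int(g))

    for i, n_i in enumerate(cfg.set_sizes):
        if len(membership[i]) > n_i:
            raise ConfigurationError(
                f"study {i}: {len(membership[i])} planted core genes exceed set size {n_i}"
            )
        chosen = membership[i]
        # fill remaining slots from the universe, skipping current members
        remaining = np.setdiff1d(np.arange(cfg.universe_size), np.fromiter(chosen, int, len(chosen)))
        extra = rng.choice(remaining, size=n_i - len(chosen), replace=False)
        membership[i] = chosen | set(int(g) for g in extra)

    return [
        GeneSet(
            study_id=f"study_{i + 1:02d}",
            symbols=frozenset(universe[sorted(members)]),
            species="synthetic",
        )
        for i, members in enumerate(membership)
    ]


def simulate_edge_table(
    symbols: Sequence[str],
    n_hubs: int = 3,
    hub_degree: int = 15,
    n_background_edges: int = 60,
    score_range: tuple[int, int] = (400, 999),
    seed: int = 0,
) -> pd.DataFrame:
    """Build a STRING-style edge table with planted hub nodes.

    Hubs each receive ``hub_degree`` partners drawn from ``symbols``;
    background edges connect random pairs.  Duplicate pairs and self-loops
    are removed, so realised hub degrees can exceed (never undershoot)
    ``hub_degree`` only via background edges.
    """
    symbols = list(dict.fromkeys(symbols))
    if n_hubs * hub_degree and len(symbols) < hub_degree + 1:
        raise ConfigurationError(
            f"need at least hub_degree+1={hub_degree + 1} symbols to plant hubs, got {len(symbols)}"
        )
    rng = np.random.default_rng(seed)
    arr = np.array(symbols)
    edges: dict[tuple[str, str], int] = {}

    def add(a: str, b: str):
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        score = int(rng.integers(score_range[0], score_range[1] + 1))
        edges[key] = max(edges.get(key, 0), score)

    hubs = rng.choice(arr, size=min(n_hubs, len(arr)), replace=False)
    for hub in hubs:
        partners = rng.choice(arr[arr != hub], size=hub_degree, replace=False)
        for p in partners:
            add(hub, p)
    for _ in range(n_background_edges):
        a, b = rng.choice(arr, size=2, replace=False)
        add(a, b)

    rows = [{"protein1": a, "protein2": b, "combined_score": s} for (a, b), s in sorted(edges.items())]
    return pd.DataFrame(rows)


def simulate_gmt(
    universe: Sequence[str],
    n_pathways: int = 20,
    size_range: tuple[int, int] = (10, 80),
    planted: dict[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Toy pathway catalogue: random gene sets plus optional planted pathways.

    ``planted`` maps a pathway id to genes that must be members (e.g. a
    block of truly regulated genes, to give enrichment something to find).
    """
    rng = np.random.default_rng(seed)
    arr = np.array(list(dict.fromkeys(universe)))
    catalog: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], min(size_range[1], len(arr)) + 1))
        members = frozenset(rng.choice(arr, size=size, replace=False))
        pid = f"PW{i + 1:04d}"
        catalog[pid] = (f"synthetic pathway {i + 1}", members)
    for pid, genes in (planted or {}).items():
        catalog[pid] = (f"planted pathway {pid}", frozenset(genes))
    return catalog
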