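"""Paired differential expression on the two-limb design.

Each animal contributes an operated (ipsilateral) and an unoperated
control (contralateral) limb, so the natural statistic is a per-probe
two-sided paired t-test on the within-animal log2 intensity differences,
followed by Benjamini-Hochberg adjustment across all tested probes of a
timepoint and collapsing of probe-level results to genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientReplicationError
from .overlap import GeneSet
from .synthetic import ExpressionExperiment

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "detect_probes", "paired_de", "collapse_probes", "volcano_classify"]


@dataclass
class DEResult:
    """Per-probe and per-gene DE statistics at one timepoint.

    ``genes`` carries one row per gene with the representative probe's
    statistics (see :func:`collapse_probes`); ``probes`` keeps the full
    probe-level table including undetected probes (stats NaN).
    """

    timepoint: str
    genes: pd.DataFrame
    probes: pd.DataFrame
    alpha: float = 0.05
    n_pairs: int = 0

    @property
    def significant_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["significant"]])

    def gene_set(self, study_id: str, species: str = "mouse") -> GeneSet:
        """Significant genes as a GeneSet with up/down direction metadata."""
        sig = self.genes[self.genes["significant"]]
        directions = {g: ("up" if lfc > 0 else "down") for g, lfc in sig["log2fc"].items()}
        return GeneSet(study_id=study_id, symbols=frozenset(sig.index), species=species,
                       directions=directions)


def detect_probes(
    exp: ExpressionExperiment,
    alpha_det: float = 0.05,
    min_fraction: float = 0.5,
    timepoint: str | None = None,
) -> pd.Series:
    """Flag probes confidently detected above background.

    A probe passes iff its detection p-value is below ``alpha_det`` in at
    least ``min_fraction`` of the samples of at least one limb group
    (detection in one limb only still counts: a transcript switched fully
    off by the intervention remains interesting).  Without detection
    p-values every probe passes, with a logged warning.
    """
    if not 0 < min_fraction <= 1:
        raise ConfigurationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    samples = exp.samples_at(timepoint) if timepoint is not None else exp.samples
    if exp.detection is None:
        logger.warning("detect_probes: no detection p-values; all %d probes pass", len(exp.matrix))
        return pd.Series(True, index=exp.matrix.index, name="detected")
    passed = pd.Series(False, index=exp.matrix.index, name="detected")
    for limb in ("ipsi", "contra"):
        cols = samples.index[samples["limb"] == limb]
        if len(cols) == 0:
            continue
        frac = (exp.detection[cols] < alpha_det).mean(axis=1)
        passed |= frac >= min_fraction
    return passed


def paired_de(
    exp: ExpressionExperiment,
    timepoint: str,
    alpha: float = 0.05,
    alpha_det: float = 0.05,
    min_fraction: float = 0.5,
) -> DEResult:
    """Two-sided paired t-test per detected probe, BH-adjusted, gene-collapsed.

    The per-probe statistic is computed on the n within-animal
    (ipsi - contra) log2 differences: t = mean(d) / (sd(d) / sqrt(n)),
    referred to a t distribution with n - 1 degrees of freedom.  At least
    three complete pairs are required.  A probe with zero variance of
    differences is degenerate: if the mean difference is also zero the
    probe is constant and gets p_raw = 1 (logged); a non-zero mean with
    zero variance is the noiseless limit of perfect separation, p_raw = 0.
    """
    samples = exp.samples_at(timepoint)
    if samples.empty:
        raise ConfigurationError(f"no samples at timepoint {timepoint!r}")
    ipsi = samples[samples["limb"] == "ipsi"].reset_index().set_index("animal_id")["sample_id"]
    contra = samples[samples["limb"] == "contra"].reset_index().set_index("animal_id")["sample_id"]
    animals = sorted(set(ipsi.index) & set(contra.index))
    if len(animals) < 3:
        raise InsufficientReplicationError(
            f"paired test at {timepoint!r} needs >= 3 complete pairs, found {len(animals)}"
        )
    detected = detect_probes(exp, alpha_det, min_fraction, timepoint=timepoint)

    mat = exp.matrix
    diffs = mat[ipsi.loc[animals].tolist()].values - mat[contra.loc[animals].tolist()].values
    n = len(animals)
    tested = detected.values
    d = diffs[tested]
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd_d == 0
    if zero_var.any():
        constant = zero_var & (mean_d == 0)
        separated = zero_var & (mean_d != 0)
        p_raw[constant] = 1.0
        p_raw[separated] = 0.0
        if constant.any():
            logger.info("paired_de[%s]: %d constant probes set to p_raw=1", timepoint, int(constant.sum()))

    p_adj = multipletests(p_raw, method="fdr_bh")[1] if len(p_raw) else np.array([])

    probes = pd.DataFrame(index=mat.index)
    probes["gene"] = exp.probe_map.reindex(mat.index)
    probes["detected"] = tested
    probes["log2fc"] = np.nan
    probes["p_raw"] = np.nan
    probes["p_adj"] = np.nan
    probes.loc[tested, "log2fc"] = mean_d
    probes.loc[tested, "p_raw"] = p_raw
    probes.loc[tested, "p_adj"] = p_adj
    probes["fold_change"] = 2.0 ** probes["log2fc"]
    probes["significant"] = probes["detected"] & (probes["p_adj"] < alpha)

    genes = collapse_probes(probes, exp.probe_map)
    return DEResult(timepoint=timepoint, genes=genes, probes=probes, alpha=alpha, n_pairs=n)


def collapse_probes(probe_results: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse probe-level DE statistics to genes.

    A gene is significant iff at least one of its probes is; its reported
    statistics come from the representative probe with minimal adjusted p,
    ties broken by larger |log2fc|, then lexicographically smaller
    probe_id — a deterministic, input-order-independent rule.
    """
    df = probe_results.copy()
    unmapped = df["gene"].isna()
    if unmapped.any():
        raise ConfigurationError(f"{int(unmapped.sum())} probes missing from probe_map")
    df = df.reset_index().rename(columns={df.index.name or "index": "probe_id"})
    df["_abs_lfc"] = -df["log2fc"].abs()  # ascending sort => larger magnitude first
    df = df.sort_values(["p_adj", "_abs_lfc", "probe_id"], na_position="last", kind="mergesort")

    grouped = df.groupby("gene", sort=True)
    rep = grouped.first()
    genes = rep[["log2fc", "fold_change", "p_raw", "p_adj"]].copy()
    genes["detected"] = grouped["detected"].any()
    genes["significant"] = grouped["significant"].any()
    genes["n_probes_collapsed"] = grouped.size()
    genes.index.name = "gene"
    # genes whose probes are all undetected keep NaN stats but stay listed
    return genes


def volcano_classify(
    de: DEResult, up_fc: float = 2.8, down_fc: float = 0.35
) -> pd.Series:
    """Partition significant genes by fold-change thresholds (volcano labels).

    Strict inequalities: a gene is ``highlighted-up`` iff significant and
    FC > up_fc, ``highlighted-down`` iff significant and FC < down_fc,
    otherwise ``other`` (non-significant genes are always ``other``).
    """
    if not 0 < down_fc < 1 < up_fc:
        raise ConfigurationError(
            f"thresholds must satisfy 0 < down_fc < 1 < up_fc, got down_fc={down_fc}, up_fc={up_fc}"
        )
    fc = de.genes["fold_change"]
    sig = de.genes["significant"]
    labels = pd.Series("other", index=de.genes.index, name="volcano")
    labels[sig & (fc > up_fc)] = "highlighted-up"
    labels[sig & (fc < down_fc)] = "highlighted-down"
    return labels
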