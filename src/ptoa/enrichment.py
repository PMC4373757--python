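"""Pathway over-representation analysis (ORA) against a GMT catalogue.

For each pathway, the number of differentially expressed genes falling in
it is referred to an upper-tail hypergeometric test: with ``N`` background
genes of which ``K`` are pathway members and ``n`` are DE, the p-value is
``P(X >= k)`` for the observed hit count ``k``.  BH adjustment runs across
all tested pathways.  The background defaults to the detected genes of the
experiment, standard ORA practice.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .overlap import GeneSet, hypergeom_overlap, venn_regions

logger = logging.getLogger(__name__)

__all__ = ["enrich", "compare_pathway_sets", "significant_pathways"]

#: pathway_id -> (name, member symbols); see :func:`ptoa.io.read_gmt`
AnnotationCatalog = Mapping[str, tuple[str, frozenset[str]]]


def enrich(
    de_genes: GeneSet | Iterable[str],
    catalog: AnnotationCatalog,
    background: GeneSet | Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each pathway.

    Genes outside the background are dropped (counted and logged);
    pathways are intersected with the background before testing, and
    pathways with no background member are skipped.  Returns one row per
    tested pathway, sorted by ``p_upper`` ascending (ties by pathway id),
    with columns ``pathway_id, name, k, K, n, N, p_upper, p_adj``.
    """
    bg = frozenset(s.upper() for s in (background.symbols if isinstance(background, GeneSet) else background))
    if not bg:
        raise ConfigurationError("background gene set is empty")
    de = frozenset(s.upper() for s in (de_genes.symbols if isinstance(de_genes, GeneSet) else de_genes))
    dropped = de - bg
    if dropped:
        logger.info("enrich: %d DE genes outside background dropped", len(dropped))
    de &= bg

    N, n = len(bg), len(de)
    rows = []
    for pid in sorted(catalog):
        name, members = catalog[pid]
        pw = frozenset(s.upper() for s in members) & bg
        K = len(pw)
        if K == 0:
            continue
        k = len(pw & de)
        res = hypergeom_overlap(k, K, n, N)
        rows.append({"pathway_id": pid, "name": name, "k": k, "K": K, "n": n, "N": N,
                     "p_upper": res.p_upper})
    result = pd.DataFrame(rows, columns=["pathway_id", "name", "k", "K", "n", "N", "p_upper"])
    if len(result):
        result["p_adj"] = multipletests(result["p_upper"], method="fdr_bh")[1]
    else:
        result["p_adj"] = []
    return result.sort_values(["p_upper", "pathway_id"], ignore_index=True)


def significant_pathways(enrichment: pd.DataFrame, alpha: float = 0.05) -> frozenset[str]:
    """Pathways with unadjusted upper-tail p below ``alpha``.

    Raw p is the reporting convention this comparison mirrors; the
    BH-adjusted column remains available in the enrichment table.
    """
    return frozenset(enrichment.loc[enrichment["p_upper"] < alpha, "pathway_id"])


def compare_pathway_sets(per_study: Mapping[str, Iterable[str]]):
    """Venn-region comparison of 2-4 studies' significant-pathway label sets."""
    sets = [
        GeneSet(study_id=study, symbols=frozenset(labels), species="n/a")
        for study, labels in per_study.items()
    ]
    return venn_regions(sets)
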