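"""Cross-study gene-list concordance statistics.

This module houses the meta-analysis core of the pipeline:

* :func:`hypergeom_overlap` — the exact hypergeometric probability mass
  function (and upper tail) of the overlap observed between two gene lists
  drawn from a common universe of ``U`` genes.
* :func:`venn_regions` — exact membership-region cardinalities for 2–4 sets.
* :func:`occurrence_histogram` — how many genes recur in exactly/at least
  ``j`` of ``S`` study lists.
* :func:`occurrence_null` — a seeded Monte-Carlo null for that histogram:
  each study list is re-drawn uniformly without replacement, at its true
  size, from a common pool of ``U`` genes, independently across studies.
* :func:`occurrence_expectation` — the closed-form (Poisson-binomial)
  expectation of the same null, used as an analytic oracle.

The occurrence null answers the question "how many genes would we expect to
see in at least *m* of *S* published osteoarthritis arrays if every array's
significant-gene list were random?"; the observed histogram lying far above
it is the concordance signal.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError, SupportError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "OverlapResult",
    "OccurrenceProfile",
    "harmonize_symbols",
    "venn_regions",
    "venn_table",
    "hypergeom_overlap",
    "overlap_log_pmf",
    "overlap_pmf_support",
    "occurrence_histogram",
    "occurrence_null",
    "occurrence_expectation",
]


@dataclass(frozen=True)
class GeneSet:
    """One study's significant gene list with light metadata.

    ``directions`` optionally records per-symbol direction of change
    ("up"/"down"); it is carried through harmonization but plays no role in
    the overlap statistics, which count membership only.
    """

    study_id: str
    symbols: frozenset[str]
    species: str = "unknown"
    directions: Mapping[str, str] | None = None

    def __post_init__(self):
        if not self.symbols:
            raise ConfigurationError(f"GeneSet {self.study_id!r}: symbols must be nonempty")
        object.__setattr__(self, "symbols", frozenset(self.symbols))

    @property
    def size(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class OverlapResult:
    """Exact hypergeometric assessment of a pairwise set overlap."""

    k: int
    n1: int
    n2: int
    U: int
    pmf: float
    p_upper: float


@dataclass
class OccurrenceProfile:
    """Observed and/or null-expected multi-study occurrence histogram.

    ``observed[j]`` counts genes present in exactly ``j`` of the ``S``
    studies (``j = 0`` is only meaningful when a universe size ``U`` is
    known); ``observed_ge[m]`` counts genes present in at least ``m``
    studies.  The ``expected*`` arrays are Monte-Carlo (or closed-form)
    means under the random-list null, with per-level simulation SDs.
    """

    S: int
    U: int | None = None
    observed: np.ndarray | None = None
    observed_ge: np.ndarray | None = None
    members: dict[int, frozenset[str]] = field(default_factory=dict)
    expected: np.ndarray | None = None
    expected_ge: np.ndarray | None = None
    sim_sd: np.ndarray | None = None
    sim_sd_ge: np.ndarray | None = None
    n_sims: int | None = None
    seed: int | None = None

    def members_at_least(self, m: int) -> frozenset[str]:
        """Genes occurring in at least ``m`` studies."""
        out: set[str] = set()
        for j, mem in self.members.items():
            if j >= m:
                out |= mem
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-level table (one row per occurrence level j)."""
        levels = np.arange(self.S + 1)
        cols: dict[str, np.ndarray] = {"occurrence": levels}
        if self.observed is not None:
            cols["observed"] = self.observed
            cols["observed_ge"] = self.observed_ge
        if self.expected is not None:
            cols["expected"] = self.expected
            cols["expected_ge"] = self.expected_ge
        if self.sim_sd is not None:
            cols["sim_sd"] = self.sim_sd
        return pd.DataFrame(cols)


def harmonize_symbols(
    sets: Sequence[GeneSet],
    ortholog_map: Mapping[str, str] | pd.DataFrame | None = None,
) -> list[GeneSet]:
    """Upper-case gene symbols and optionally translate through an ortholog map.

    Cross-species comparison (mouse/rat/human lists) requires a common symbol
    space; the convention adopted here is upper-cased human-style symbols.
    Unmapped symbols are kept as their upper-cased originals (counted and
    logged); duplicates arising from many-to-one mapping are collapsed.
    """
    mapping: dict[str, str] = {}
    if ortholog_map is not None:
        if isinstance(ortholog_map, pd.DataFrame):
            rows = ortholog_map.iloc[:, :2].itertuples(index=False)
        else:
            rows = ortholog_map.items()
        for row in rows:
            try:
                src, dst = row
            except ValueError:
                logger.warning("harmonize_symbols: malformed ortholog map row %r skipped", row)
                continue
            if not isinstance(src, str) or not isinstance(dst, str) or not src or not dst:
                logger.warning("harmonize_symbols: malformed ortholog map row %r skipped", row)
                continue
            mapping[src.upper()] = dst.upper()

    out = []
    for gs in sets:
        translated = {mapping.get(s.upper(), s.upper()) for s in gs.symbols}
        n_unmapped = sum(1 for s in gs.symbols if mapping and s.upper() not in mapping)
        n_collapsed = len(gs.symbols) - len(translated)
        if mapping and n_unmapped:
            logger.info(
                "harmonize_symbols: %s — %d symbols not in ortholog map, kept upper-cased",
                gs.study_id, n_unmapped,
            )
        if n_collapsed:
            logger.info(
                "harmonize_symbols: %s — %d symbols collapsed by mapping", gs.study_id, n_collapsed
            )
        directions = None
        if gs.directions is not None:
            directions = {mapping.get(k.upper(), k.upper()): v for k, v in gs.directions.items()}
        out.append(GeneSet(gs.study_id, frozenset(translated), gs.species, directions))
    return out


def venn_regions(sets: Sequence[GeneSet]) -> dict[tuple[str, ...], frozenset[str]]:
    """Exact membership regions for 2–4 gene sets.

    Returns a mapping from the tuple of study ids defining a region (the
    studies a member belongs to, all others excluded) to the region's member
    set.  All ``2**S - 1`` regions are present, empty or not, and their
    cardinalities sum to the union size.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_regions supports 2-4 sets, got {len(sets)}")
    ids = [gs.study_id for gs in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("venn_regions: study_ids must be distinct")
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inside = frozenset.intersection(*[sets[i].symbols for i in combo])
            outside = frozenset().union(
                *[sets[i].symbols for i in range(len(sets)) if i not in combo]
            )
            regions[tuple(ids[i] for i in combo)] = frozenset(inside - outside)
    return regions


def venn_table(regions: dict[tuple[str, ...], frozenset[str]]) -> pd.DataFrame:
    """Region counts and member lists as a tidy table."""
    rows = [
        {
            "region": "&".join(key),
            "n_sets": len(key),
            "count": len(members),
            "members": ",".join(sorted(members)),
        }
        for key, members in sorted(regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows)


def _log_binom(n, k):
    """log C(n, k) via log-gamma; universes of ~20,000 overflow factorials."""
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def overlap_log_pmf(k, n1: int, n2: int, U: int):
    """Vectorised log p.m.f. of the overlap; ``k`` may be an array.

    Log-gamma formulation, useful for tails too deep for :func:`overlap_pmf_support`
    to represent in linear space.
    """
    k = np.asarray(k)
    return _log_binom(n1, k) + _log_binom(U - n1, n2 - k) - _log_binom(U, n2)


def overlap_pmf_support(n1: int, n2: int, U: int) -> tuple[np.ndarray, np.ndarray]:
    """p.m.f. of the overlap over its whole support, near machine precision.

    Anchors the probability at the distribution's mode with exact integer
    binomial coefficients and propagates outwards with the term ratio

        pmf(k+1)/pmf(k) = (n1-k)(n2-k) / ((k+1)(U-n1-n2+k+1)),

    so the support sums to one to ~1e-15 even for universes of tens of
    thousands of genes.  Returns ``(support, pmf)``.
    """
    if not (0 <= n1 <= U and 0 <= n2 <= U):
        raise ConfigurationError(f"set sizes must satisfy 0 <= n1, n2 <= U; got n1={n1}, n2={n2}, U={U}")
    lo, hi = max(0, n1 + n2 - U), min(n1, n2)
    ks = np.arange(lo, hi + 1)
    if len(ks) == 1:
        return ks, np.ones(1)
    mode = min(max(int((n1 + 1) * (n2 + 1) // (U + 2)), lo), hi)
    anchor = float(Fraction(
        math.comb(n1, mode) * math.comb(U - n1, n2 - mode), math.comb(U, n2)
    ))
    vals = np.empty(len(ks))
    im = mode - lo
    vals[im] = anchor
    kf = ks.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ((n1 - kf) * (n2 - kf)) / ((kf + 1) * (U - n1 - n2 + kf + 1))
    if im + 1 < len(ks):
        vals[im + 1:] = anchor * np.cumprod(ratio[im:-1])
    if im > 0:
        vals[:im] = (anchor * np.cumprod(1.0 / ratio[im - 1::-1]))[::-1]
    return ks, vals


def hypergeom_overlap(k: int, n1: int, n2: int, U: int) -> OverlapResult:
    """Exact hypergeometric p.m.f. and upper tail of a pairwise overlap.

    Models the overlap between a fixed set of ``n1`` genes and a uniformly
    random set of ``n2`` genes from a universe of ``U``:

        P(X = k) = C(n1, k) C(U - n1, n2 - k) / C(U, n2)

    computed in log space.  ``pmf`` is the point probability of the
    observed overlap (the quantity the source analyses plot);
    ``p_upper = P(X >= k)`` is the conventional one-sided enrichment
    p-value, accumulated over the upper support.
    """
    if not (0 <= n1 <= U and 0 <= n2 <= U):
        raise ConfigurationError(f"set sizes must satisfy 0 <= n1, n2 <= U; got n1={n1}, n2={n2}, U={U}")
    lo, hi = max(0, n1 + n2 - U), min(n1, n2)
    if not lo <= k <= hi:
        raise SupportError(f"overlap k={k} outside support [{lo}, {hi}] for n1={n1}, n2={n2}, U={U}")
    ks, pmf = overlap_pmf_support(n1, n2, U)
    return OverlapResult(
        k=k, n1=n1, n2=n2, U=U,
        pmf=float(pmf[k - lo]),
        p_upper=float(min(math.fsum(pmf[k - lo:]), 1.0)),
    )


def occurrence_histogram(sets: Sequence[GeneSet], U: int | None = None) -> OccurrenceProfile:
    """Observed multi-study occurrence histogram over the union of the sets.

    ``sets`` are assumed harmonized to a shared symbol space.  With a
    universe size ``U`` the ``j = 0`` level counts the ``U - |union|``
    never-seen genes; without it the level is zero by convention.
    """
    S = len(sets)
    counts: dict[str, int] = {}
    for gs in sets:
        for sym in gs.symbols:
            counts[sym] = counts.get(sym, 0) + 1
    observed = np.zeros(S + 1, dtype=float)
    members: dict[int, set[str]] = {}
    for sym, j in counts.items():
        observed[j] += 1
        members.setdefault(j, set()).add(sym)
    if U is not None:
        union = len(counts)
        if union > U:
            raise ConfigurationError(f"universe U={U} smaller than union of sets ({union})")
        observed[0] = U - union
    observed_ge = np.cumsum(observed[::-1])[::-1]
    return OccurrenceProfile(
        S=S, U=U, observed=observed, observed_ge=observed_ge,
        members={j: frozenset(m) for j, m in members.items()},
    )


def occurrence_null(
    set_sizes: Sequence[int],
    U: int,
    n_sims: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    _batch: int = 256,
) -> OccurrenceProfile:
    """Monte-Carlo occurrence null: random same-sized lists from a common pool.

    For each replicate, every study ``i`` independently draws ``n_i``
    distinct genes uniformly without replacement from a pool of ``U``;
    genes are tabulated by the number of studies containing them.
    ``expected[j]`` / ``sim_sd[j]`` are the mean / SD over replicates, and
    the ``*_ge`` arrays the same for the at-least-``j`` tail.  Fully seeded:
    identical seeds give bit-identical profiles.
    """
    sizes = np.asarray(list(set_sizes), dtype=int)
    S = len(sizes)
    if n_sims < 1:
        raise ConfigurationError(f"n_sims must be >= 1, got {n_sims}")
    if (sizes < 0).any() or (sizes > U).any():
        raise ConfigurationError(f"set sizes must lie in [0, U={U}]; got {sizes.tolist()}")
    rng = np.random.default_rng(seed)

    sum_j = np.zeros(S + 1)
    sumsq_j = np.zeros(S + 1)
    sum_ge = np.zeros(S + 1)
    sumsq_ge = np.zeros(S + 1)

    done = 0
    while done < n_sims:
        b = min(_batch, n_sims - done)
        occ = np.zeros((b, U), dtype=np.int8)
        for n_i in sizes:
            if n_i == 0:
                continue
            # rank trick: the n_i smallest of U iid uniforms per row form a
            # uniform without-replacement draw of size n_i
            keys = rng.random((b, U))
            idx = np.argpartition(keys, n_i - 1, axis=1)[:, :n_i]
            member = np.zeros((b, U), dtype=bool)
            np.put_along_axis(member, idx, True, axis=1)
            occ += member
        hist = np.empty((b, S + 1))
        for j in range(S + 1):
            hist[:, j] = (occ == j).sum(axis=1)
        ge = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]
        sum_j += hist.sum(axis=0)
        sumsq_j += (hist ** 2).sum(axis=0)
        sum_ge += ge.sum(axis=0)
        sumsq_ge += (ge ** 2).sum(axis=0)
        done += b

    def _mean_sd(s, ss):
        mean = s / n_sims
        var = np.maximum(ss / n_sims - mean ** 2, 0.0)
        if n_sims > 1:
            var *= n_sims / (n_sims - 1)
        return mean, np.sqrt(var)

    expected, sim_sd = _mean_sd(sum_j, sumsq_j)
    expected_ge, sim_sd_ge = _mean_sd(sum_ge, sumsq_ge)
    seed_val = seed if isinstance(seed, int) else None
    return OccurrenceProfile(
        S=S, U=U, expected=expected, expected_ge=expected_ge,
        sim_sd=sim_sd, sim_sd_ge=sim_sd_ge, n_sims=n_sims, seed=seed_val,
    )


def occurrence_expectation(set_sizes: Sequence[int], U: int) -> np.ndarray:
    """Closed-form expected occurrence histogram under the random-list null.

    A fixed gene belongs to study ``i`` with marginal probability
    ``p_i = n_i / U`` (the within-study without-replacement draw does not
    change a single gene's marginal), independently across studies, so its
    occurrence count follows a Poisson-binomial distribution.  The expected
    histogram is ``U * P(PB(p_1..p_S) = j)``, computed by the standard
    O(S^2) convolution recursion.
    """
    sizes = np.asarray(list(set_sizes), dtype=float)
    if (sizes < 0).any() or (sizes > U).any():
        raise ConfigurationError(f"set sizes must lie in [0, U={U}]; got {list(set_sizes)}")
    probs = sizes / U
    coeffs = np.array([1.0])
    for p in probs:
        new = np.zeros(len(coeffs) + 1)
        new[:-1] += coeffs * (1.0 - p)
        new[1:] += coeffs * p
        coeffs = new
    return U * coeffs
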