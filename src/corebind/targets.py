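"""Direct-target definition and gene-set enrichment.

A direct target is a gene both bound (assigned a reconciled core binding
interval) and differentially expressed in the mutant.  Term enrichment is
an upper-tail hypergeometric test with Holm-Bonferroni family-wise
correction; an optional gene-length correction replaces the hypergeometric
null with length-proportional resampling, cancelling the bias of long
genes accumulating more binding intervals under uniform binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import holm_bonferroni

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetGene:
    gene_id: str
    direction: str  # "up" | "down"
    aveM: float
    supporting_intervals: tuple[str, ...] = ()


def define_targets(
    bound: Set[str],
    de: pd.DataFrame,
    hits: Optional[Sequence] = None,
) -> list[TargetGene]:
    """Intersect the bound gene set with the up/down DE calls.

    ``de`` is the frame produced by :func:`corebind.expression.call_de`.
    ``hits`` (optional) are :class:`corebind.assign.GeneHit` records used
    to attach supporting interval ids.
    """
    support: dict[str, list[str]] = {}
    if hits is not None:
        for h in hits:
            support.setdefault(h.gene_id, []).append(h.interval_id)
    called = de[de["call"].isin(["up", "down"])]
    out = []
    for row in called.itertuples(index=False):
        if row.gene_id in bound:
            out.append(
                TargetGene(
                    gene_id=row.gene_id,
                    direction=row.call,
                    aveM=float(row.aveM),
                    supporting_intervals=tuple(support.get(row.gene_id, ())),
                )
            )
    out.sort(key=lambda t: t.gene_id)
    return out


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: annotated genes in the query, n: query size, K: term size in the
    universe, N: universe size.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adjusted: float
    method: str  # "hypergeometric" | "length_corrected"


def enrich_terms(
    query: Set[str],
    terms: Mapping[str, Set[str]],
    universe: Set[str],
    correction: str = "none",
    gene_lengths: Optional[Mapping[str, float]] = None,
    resamples: int = 10_000,
    seed: Optional[int] = None,
) -> list[EnrichmentResult]:
    """Test each term for over-representation in the query gene set.

    correction="none": exact hypergeometric upper tail.
    correction="length": empirical p from ``resamples`` random gene sets of
    the query's size drawn without replacement with selection probability
    proportional to gene length; p = (1 + #{k* >= k}) / (R + 1).
    Either way the Holm-Bonferroni correction is applied across the terms
    tested in this call.  Query genes outside the universe are dropped
    with a warning; terms empty within the universe are skipped.
    """
    universe_sorted = sorted(universe)
    N = len(universe_sorted)
    dropped = query - universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    query_in = query & universe
    n = len(query_in)

    term_names, ks, Ks = [], [], []
    term_sets = []
    for term, genes in terms.items():
        genes_in = set(genes) & universe
        if not genes_in:
            logger.warning("term %s has no genes in the universe; skipped", term)
            continue
        term_names.append(term)
        term_sets.append(genes_in)
        ks.append(len(query_in & genes_in))
        Ks.append(len(genes_in))
    if not term_names:
        return []

    if correction == "none":
        p_raw = [hypergeom_test(k, n, K, N) for k, K in zip(ks, Ks)]
        method = "hypergeometric"
    elif correction == "length":
        if resamples < 1:
            raise ValueError("length correction needs resamples >= 1")
        if gene_lengths is None:
            raise ValueError("length correction needs gene_lengths")
        lengths = np.array([float(gene_lengths[g]) for g in universe_sorted])
        if np.any(lengths <= 0):
            raise ValueError("gene lengths must be positive")
        rng = np.random.default_rng(seed)
        # weighted sampling without replacement via Gumbel top-k keys
        logw = np.log(lengths)
        membership = np.column_stack(
            [np.isin(universe_sorted, sorted(t)) for t in term_sets]
        )  # N x T
        exceed = np.zeros(len(term_names), dtype=int)
        ks_arr = np.array(ks)
        batch = max(1, min(resamples, int(2e7 / max(N, 1))))
        done = 0
        while done < resamples:
            b = min(batch, resamples - done)
            keys = logw[None, :] + rng.gumbel(size=(b, N))
            top = np.argpartition(keys, -n, axis=1)[:, -n:] if n > 0 else np.empty((b, 0), int)
            counts = membership[top].sum(axis=1)  # b x T
            exceed += np.sum(counts >= ks_arr[None, :], axis=0)
            done += b
        p_raw = ((1 + exceed) / (resamples + 1)).tolist()
        method = "length_corrected"
    else:
        raise ValueError(f"unknown correction {correction!r}")

    p_adj = holm_bonferroni(p_raw)
    return [
        EnrichmentResult(term, k, n, K, N, float(pr), float(pa), method)
        for term, k, K, pr, pa in zip(term_names, ks, Ks, p_raw, p_adj)
    ]


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
            }
            for r in results
        ]
    )


def map_orthologues(
    source_genes: Set[str],
    table: Sequence[tuple[str, str]],
    compare_to: Set[str],
) -> tuple[Set[str], int]:
    """Expand source genes through a (possibly many-to-many) orthologue
    table and count the overlap with a comparison set.

    Returns (mapped set, |mapped & compare_to|).
    """
    mapped = {dst for src, dst in table if src in source_genes}
    return mapped, len(mapped & compare_to)


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV: term, gene."""
    terms: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
    for row in df.itertuples(index=False):
        terms.setdefault(str(row.term), set()).add(str(row.gene))
    return terms
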