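"""Hypergeometric over-representation analysis of DAP sets.

The background universe is the quantified protein set of the experiment
(not the whole genome), intersected with the annotated universe; proteins
without any pathway annotation are excluded from both the DAP set size n
and the background size N.  For each pathway with K annotated background
members and k DAP members:

    fold enrichment = (k / n) / (K / N)
    p = P(X >= k),  X ~ Hypergeometric(N, K, n)  (upper tail)

with Benjamini-Hochberg adjustment across the tested pathways of one run
(one directional DAP set x one annotation collection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationSets
from .differential import bh_adjust

logger = logging.getLogger("proteoheat")


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    k: int            # DAPs in pathway
    n: int            # annotated DAP set size
    K: int            # background members in pathway
    N: int            # annotated background size
    fold_enrichment: float
    p: float
    q: float = np.nan


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(dap_set, annotations: AnnotationSets, background,
           min_size: int = 3) -> pd.DataFrame:
    """Over-representation of a DAP set against the quantified background.

    ``dap_set`` and ``background`` are iterables of protein ids; both are
    intersected with the annotated universe before testing.  Pathways with
    fewer than ``min_size`` background members are dropped.  Returns a
    table sorted by q then fold enrichment (descending).
    """
    universe = annotations.universe()
    bg = frozenset(background) & universe
    daps = frozenset(dap_set) & bg
    dropped_daps = len(frozenset(dap_set)) - len(frozenset(dap_set) & frozenset(background))
    if dropped_daps:
        logger.info("enrich: %d DAP(s) outside the background were dropped", dropped_daps)
    logger.info(
        "enrich: %d annotated DAPs against annotated background of %d "
        "(universe intersection)", len(daps), len(bg),
    )
    N, n = len(bg), len(daps)
    results: list[EnrichmentResult] = []
    if n == 0:
        logger.warning("enrich: empty annotated DAP set; returning no results")
        return _to_frame(results)
    skipped = 0
    for pid in annotations.members:
        members = annotations.members[pid] & bg
        K = len(members)
        if K < min_size:
            skipped += 1
            continue
        k = len(members & daps)
        fold = (k / n) / (K / N)
        p = hypergeom_upper_tail(k, N, K, n)
        results.append(EnrichmentResult(
            pathway_id=pid, name=annotations.names.get(pid, ""),
            k=k, n=n, K=K, N=N, fold_enrichment=fold, p=p,
        ))
    if skipped:
        logger.info("enrich: skipped %d pathway(s) below min_size=%d", skipped, min_size)
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return _to_frame(results)


def _to_frame(results) -> pd.DataFrame:
    cols = ["pathway_id", "name", "k", "n", "K", "N", "fold_enrichment", "p", "q"]
    if not results:
        return pd.DataFrame(columns=cols).set_index("pathway_id")
    df = pd.DataFrame([r.__dict__ for r in results], columns=cols)
    df = df.sort_values(["q", "fold_enrichment"], ascending=[True, False],
                        kind="mergesort")
    return df.set_index("pathway_id")
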