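"""Detection-method feature matrix and method-type enrichment.

The feature matrix is binary: interactions x retained detection methods,
cell = 1 iff the method is in the interaction's ancestor-closed method set.
Retention rules drop (i) type-specific assays (the enzymatic-study subtree,
which would make prediction circular), (ii) rare methods annotated to fewer
than ``min_count`` interactions, and (iii) universal methods annotated to
every interaction.  Over/under-representation of each interaction type
among each method's interactions is scored with exact hypergeometric tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .interactions import UniqueInteraction
from .ontology import Ontology

__all__ = [
    "EnrichmentResult",
    "build_feature_matrix",
    "hypergeometric_tail",
    "method_type_enrichment",
    "enrichment_table",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric over/under-representation of one (method, type) pair.

    k interactions carry both annotations, out of K with the type, n with
    the method, N in the universe.  ``p_enrich`` = P[X >= k] and
    ``p_deplete`` = P[X <= k] for X ~ Hypergeom(N, K, n); the two tails
    share the point mass at k, so they sum to >= 1.
    """

    method: str
    itype: str
    k: int
    K: int
    n: int
    N: int
    p_enrich: float
    p_deplete: float


def build_feature_matrix(
    interactions: Sequence[UniqueInteraction],
    exclusion_root: str | None = None,
    min_count: int = 200,
    ontology_methods: Ontology | None = None,
) -> pd.DataFrame:
    """Binary interactions x detection-methods matrix under the filter rules.

    Parameters
    ----------
    exclusion_root:
        Detection-method term whose whole subtree (the type-specific
        enzymatic assays) is excluded from the columns; requires
        ``ontology_methods``.
    min_count:
        Methods whose closed-set count is below this are dropped as rare
        (default 200).

    Returns a DataFrame indexed by pair id with sorted, stable columns.
    Raises if no column survives.
    """
    counts: dict[str, int] = {}
    for ui in interactions:
        for m in ui.methods_closed:
            counts[m] = counts.get(m, 0) + 1
    excluded: frozenset[str] = frozenset()
    if exclusion_root is not None:
        if ontology_methods is None:
            raise ValueError("exclusion_root requires ontology_methods")
        excluded = ontology_methods.subtree(exclusion_root)
    n_total = len(interactions)
    cols = sorted(
        m
        for m, c in counts.items()
        if m not in excluded and c >= min_count and c < n_total
    )
    if not cols:
        raise ValueError("no detection-method feature survives filtering")
    col_pos = {m: j for j, m in enumerate(cols)}
    data = np.zeros((n_total, len(cols)), dtype=np.int8)
    index = []
    for i, ui in enumerate(interactions):
        index.append(ui.pair_id)
        for m in ui.methods_closed:
            j = col_pos.get(m)
            if j is not None:
                data[i, j] = 1
    return pd.DataFrame(data, index=index, columns=cols)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact hypergeometric tails (P[X >= k], P[X <= k]).

    X counts type-K successes in a draw of n from a universe of N.
    Inconsistent counts raise.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError(f"k={k} outside support for K={K}, n={n}, N={N}")
    if N == 0:
        return 1.0, 1.0  # empty universe: X is degenerate at 0
    rv = hypergeom(N, K, n)
    p_enrich = float(rv.sf(k - 1))
    p_deplete = float(rv.cdf(k))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def method_type_enrichment(
    interactions: Sequence[UniqueInteraction],
    matrix: pd.DataFrame,
    type_universe: Iterable[str] | None = None,
    use_closed_types: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each interaction type per retained method.

    The universe is the interactions present in ``matrix``.  Types default
    to every term annotated (closed) to at least one such interaction; pass
    ``use_closed_types=False`` to count direct annotations only.
    """
    by_id = {ui.pair_id: ui for ui in interactions}
    ids = [i for i in matrix.index if i in by_id]
    type_sets = {
        i: (by_id[i].types_closed if use_closed_types else by_id[i].types_direct)
        for i in ids
    }
    if type_universe is None:
        seen: set[str] = set()
        for ts in type_sets.values():
            seen |= ts
        types = sorted(seen)
    else:
        types = sorted(set(type_universe))
    N = len(ids)
    K_count = {t: sum(1 for i in ids if t in type_sets[i]) for t in types}
    results = []
    for method in matrix.columns:
        has_method = matrix.loc[ids, method].to_numpy(dtype=bool)
        n = int(has_method.sum())
        for t in types:
            if K_count[t] == 0:
                continue
            k = sum(
                1 for i, flag in zip(ids, has_method) if flag and t in type_sets[i]
            )
            p_en, p_de = hypergeometric_tail(k, K_count[t], n, N)
            results.append(
                EnrichmentResult(
                    method=method, itype=t, k=k, K=K_count[t], n=n, N=N,
                    p_enrich=p_en, p_deplete=p_de,
                )
            )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results, adding Benjamini-Hochberg q-values.

    The q-value columns are a convenience on top of the raw tails and are
    not part of the core procedure, which reports raw p-values.
    """
    df = pd.DataFrame(
        {
            "method": [r.method for r in results],
            "itype": [r.itype for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_enrich": [r.p_enrich for r in results],
            "p_deplete": [r.p_deplete for r in results],
        }
    )
    if len(df):
        df["q_enrich"] = multipletests(df["p_enrich"], method="fdr_bh")[1]
        df["q_deplete"] = multipletests(df["p_deplete"], method="fdr_bh")[1]
    return df.sort_values("p_enrich", kind="stable").reset_index(drop=True)
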