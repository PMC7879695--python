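"""Gene-set over-representation analysis (ORA).

A differentially expressed gene list is tested against each set of a GMT
collection with the one-sided hypergeometric upper tail
P(X >= k) for X ~ Hypergeometric(N, K, n): N background genes, K of them in
the set, n in the DE list, k in both. The tail is summed exactly in log
space. The default background is every mRNA symbol on the array annotation.
p-values are Benjamini-Hochberg adjusted across all tested sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust
from .errors import ValidationError
from .io_formats import GeneSetCollection


@dataclass
class EnrichmentResult:
    set_name: str
    k_overlap: int
    K_set: int
    n_list: int
    N_universe: int
    p_value: float
    adj_p: float
    gene_ratio: float
    overlap_symbols: tuple[str, ...]


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), via log-space
    summation of the tail."""
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N or k > min(K, n):
        raise ValidationError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    js = np.arange(k, min(K, n) + 1)
    log_pmf = _log_comb(K, js) + _log_comb(N - K, n - js) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _dedupe(symbols: Sequence[str]) -> list[str]:
    return list(dict.fromkeys(symbols))


def ora(
    de_symbols: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
    top: int | None = None,
) -> list[EnrichmentResult]:
    """Over-representation of a DE gene list in each set of a collection.

    Symbols outside the universe are dropped (with a warning count); sets
    with no member in the universe are not tested. Results come back sorted
    by p ascending (ties by set name), truncated to ``top`` when given.
    """
    universe_list = _dedupe(universe)
    if not universe_list:
        raise ValidationError("universe must be non-empty")
    uni = set(universe_list)
    de_all = _dedupe(de_symbols)
    de_in = [g for g in de_all if g in uni]
    dropped = len(de_all) - len(de_in)
    if dropped:
        warnings.warn(
            f"{dropped} DE symbols outside the universe were dropped",
            stacklevel=2,
        )
    if not de_in:
        warnings.warn("empty DE list after universe intersection", stacklevel=2)
        return []
    de_set = set(de_in)
    N = len(universe_list)
    n_list = len(de_in)
    results: list[EnrichmentResult] = []
    for gs in sets:
        members_in = [g for g in _dedupe(gs.members) if g in uni]
        K = len(members_in)
        if K == 0:
            continue
        overlap = tuple(g for g in members_in if g in de_set)
        k = len(overlap)
        p = hypergeom_upper_tail(k, K, n_list, N)
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                k_overlap=k,
                K_set=K,
                n_list=n_list,
                N_universe=N,
                p_value=p,
                adj_p=np.nan,
                gene_ratio=k / n_list,
                overlap_symbols=overlap,
            )
        )
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    if top is not None:
        results = results[:top]
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = asdict(r)
        row["overlap_symbols"] = ",".join(r.overlap_symbols)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "k_overlap",
            "K_set",
            "n_list",
            "N_universe",
            "p_value",
            "adj_p",
            "gene_ratio",
            "overlap_symbols",
        ],
    )


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    enrichment_to_frame(results).to_csv(path, sep="\t", index=False)
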