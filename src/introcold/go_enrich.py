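"""Over-representation analysis against a flat GO-slim style annotation.

For a study set of *n* genes drawn from a population of *N*, a term
annotating *K* population genes and *k* study genes is scored with the
exact upper hypergeometric tail P(X >= k), X ~ Hypergeom(N, K, n).
Benjamini-Hochberg adjustment is applied across the tested terms; the raw
p is reported alongside.  Annotation is taken as a flat term -> gene map
(GMT); ontology-graph propagation, if desired, must be pre-applied.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import GeneSet
from .sam_test import ContractError


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: study-set genes carrying the term, n: study-set size, K: population
    genes carrying the term, N: population size.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ContractError(
            f"hypergeometric bounds violated: k={k}, n={n}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    study: Iterable[str],
    annotation: Mapping[str, GeneSet] | Mapping[str, Iterable[str]],
    population: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of each annotated term in the study set.

    Unannotated genes count toward N but toward no K.  Only terms with at
    least one study hit are reported, sorted by raw p (ties by term id).
    """
    population = set(population)
    study = set(study)
    outside = study - population
    if outside:
        raise ContractError(
            f"{len(outside)} study genes outside the population (e.g. {sorted(outside)[0]!r})"
        )
    N, n = len(population), len(study)
    rows = []
    for term in sorted(annotation):
        entry = annotation[term]
        genes = set(entry.genes if isinstance(entry, GeneSet) else entry) & population
        K = len(genes)
        k = len(genes & study)
        if k == 0:
            continue
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fraction": k / n if n else 0.0,
                "p_value": hypergeom_tail(k, n, K, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "fraction", "p_value", "p_adjusted"]
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    return df
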