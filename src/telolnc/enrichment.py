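"""Annotation-term over-representation by the hypergeometric upper tail.

A query gene set (e.g. genes whose expression correlates with a neighboring
lncRNA) is tested against each term of a user-supplied term -> gene map; the
universe defaults to all genes carrying an expression profile, guarding
against detection bias.  P-values are Benjamini-Hochberg adjusted across
the tested terms.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class TermMap:
    terms: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.universe = frozenset(self.universe)
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term}: genes outside the universe")


def read_term_map(path: str | os.PathLike, universe=None) -> TermMap:
    """Read a two-column TSV (term_id <TAB> gene_id).  When a universe is
    given, term genes outside it are dropped; otherwise the universe is the
    union of all term genes."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                        dtype=str, comment="#")
    terms: dict[str, set[str]] = {}
    for row in frame.itertuples():
        terms.setdefault(row.term_id, set()).add(row.gene_id)
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    else:
        universe = set(universe)
        terms = {t: g & universe for t, g in terms.items()}
    return TermMap(terms={t: frozenset(g) for t, g in terms.items()},
                   universe=frozenset(universe))


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability of >= k hits when drawing n
    genes from a universe of N containing K term members."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1, evaluated stably in log space by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query, term_map: TermMap, alpha: float = 0.05) -> pd.DataFrame:
    """One row per term with K >= 1 members: hit count, hypergeometric p,
    BH-adjusted q and fold enrichment, sorted by (q, p, term)."""
    universe = term_map.universe
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    dropped = query - universe
    if dropped:
        log.info("dropping %d query genes outside the universe: %s",
                 len(dropped), sorted(dropped)[:5])
    query &= universe
    N, n = len(universe), len(query)

    rows = []
    for term in sorted(term_map.terms):
        members = term_map.terms[term]
        K = len(members)
        if K < 1:
            continue
        k = len(query & members)
        p = hypergeometric_p(k, K, n, N)
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "fold_enrichment": fold, "p": p})
    frame = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N",
                                        "fold_enrichment", "p"])
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["q"] = pd.Series(dtype=float)
    frame = frame.sort_values(["q", "p", "term"]).reset_index(drop=True)
    frame["significant"] = frame["q"] < alpha
    return frame
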