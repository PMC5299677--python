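"""Gene-set over-representation: Fisher's exact test over a GMT collection
with Bonferroni correction, and hypergeometric trait-association enrichment.

The one-sided Fisher p on the 2x2 (in-query x in-term) table equals the
hypergeometric upper tail of the overlap; tails are computed in log space
(scipy ``hypergeom.logsf``) so enrichments far beyond 1e-300 survive.
With the default alpha 0.05 over an 825-term biological-process
collection, the Bonferroni significance threshold is 0.05/825 ~ 6.1e-5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "fisher_enrichment",
    "hypergeom_trait_enrichment",
    "go_bonferroni_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they live in.

    Gene symbols are upper-cased on construction; set members outside the
    universe are dropped when a universe is given explicitly.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = {g.upper() for g in self.universe}
        self.sets = {name: {g.upper() for g in members} & self.universe
                     for name, members in self.sets.items()}

    @property
    def n_terms(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict to a measured-gene universe (e.g. the expression panel)."""
        uni = {g.upper() for g in universe} & self.universe
        return GeneSetCollection({n: s for n, s in self.sets.items()}, uni)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members."""
    sets: dict[str, set[str]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT needs name, description and at least one member")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            members = {g.strip().upper() for g in fields[2:] if g.strip()}
            sets[name] = members
            universe |= members
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, universe)


@dataclass
class EnrichmentResult:
    term: str
    k_overlap: int
    n_query: int
    K_set: int
    N_universe: int
    p: float
    log10_p: float
    significant: bool


def go_bonferroni_threshold(alpha: float, n_terms: int) -> float:
    """Per-term significance threshold alpha / number-of-terms."""
    if n_terms <= 0:
        raise ValueError("collection has no terms")
    return alpha / n_terms


def _hypergeom_upper_log(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k) for X ~ Hypergeom(N, K, n); exact 0 overlap gives log 1."""
    if k <= 0:
        return 0.0
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.logsf(k - 1, N, K, n))


def fisher_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation of the query in each term.

    Query genes outside the universe are dropped with a warning.  A term
    is significant iff p < alpha / n_terms (Bonferroni across the
    collection).  Results sorted by ascending p.
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    q = {g.upper() for g in query}
    dropped = q - collection.universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped",
            stacklevel=2)
    q &= collection.universe
    N = len(collection.universe)
    n = len(q)
    thresh = go_bonferroni_threshold(alpha, collection.n_terms)
    out = []
    for term, members in collection.sets.items():
        K = len(members)
        k = len(q & members)
        if alternative == "greater":
            logp = _hypergeom_upper_log(k, N, K, n)
            p = float(np.exp(logp))
        elif alternative == "two-sided":
            a, b = k, n - k
            c, d = K - k, N - K - (n - k)
            p = float(stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")[1])
            logp = float(np.log(max(p, 5e-324)))
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        p = min(max(p, 5e-324), 1.0)
        out.append(EnrichmentResult(term=term, k_overlap=k, n_query=n,
                                    K_set=K, N_universe=N, p=p,
                                    log10_p=logp / np.log(10),
                                    significant=p < thresh))
    out.sort(key=lambda r: (r.p, r.log10_p))
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.k_overlap for r in results],
            "n": [r.n_query for r in results],
            "K": [r.K_set for r in results],
            "N": [r.N_universe for r in results],
            "p": [r.p for r in results],
            "log10_p": [r.log10_p for r in results],
            "bonferroni_significant": [r.significant for r in results],
        }
    )


def hypergeom_trait_enrichment(
    coexpressed: Iterable[str],
    trait_associated: Iterable[str],
    universe_size: int,
) -> float:
    """Upper-tail hypergeometric p of the coexpressed/trait-set overlap.

    Models the coexpressed set as a draw of size n from a universe of
    ``universe_size`` genes containing K trait-associated genes.
    """
    co = {g.upper() for g in coexpressed}
    tr = {g.upper() for g in trait_associated}
    k = len(co & tr)
    n, K, N = len(co), len(tr), int(universe_size)
    if n > N or K > N:
        raise ValueError("set sizes exceed the universe")
    if k > min(n, K):
        raise ValueError("overlap exceeds set sizes (inconsistent input)")
    return float(min(np.exp(_hypergeom_upper_log(k, N, K, n)), 1.0))
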