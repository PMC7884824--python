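"""Hypergeometric over-representation analysis of gene sets.

The upper-tail p-value P(X >= k) is computed with the survival function of
the hypergeometric distribution (evaluated in log space by scipy), and sets
with raw p < alpha (default 0.05) are flagged significant.  A
Benjamini-Hochberg adjusted column is emitted alongside but does not drive
the significance flag.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "run_enrichment",
    "read_gmt",
    "write_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        genes = frozenset(g.upper() for g in self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", genes)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against.

    The background defaults to the union of all member genes; a user-supplied
    universe overrides it.
    """

    sets: list[GeneSet]
    background: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("gene set names must be unique")
        if self.background is None:
            union: set[str] = set()
            for s in self.sets:
                union |= s.genes
            self.background = frozenset(union)
        else:
            self.background = frozenset(g.upper() for g in self.background)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    k: int  # overlap
    K: int  # set size (within background)
    n: int  # query size (within background)
    N: int  # background size
    p: float
    p_bh: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def run_enrichment(
    query: Iterable[str],
    coll: GeneSetCollection,
    alpha: float = 0.05,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test the query gene set against every set in the collection.

    Query genes outside the background are dropped with a warning.  Results
    come back sorted by p ascending; the significant flag applies strict
    p < ``alpha`` to the raw p-value.  ``ease`` subtracts one success from
    the overlap (DAVID's conservative EASE variant); off by default.
    """
    query = {g.upper() for g in query}
    if not query:
        raise ValueError("empty query gene set")
    if not coll.sets:
        raise ValueError("empty gene set collection")
    background = coll.background
    assert background is not None
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped"
        )
        query &= background
    if not query:
        raise ValueError("no query genes remain within the background")

    N = len(background)
    n = len(query)
    rows = []
    for s in coll.sets:
        members = s.genes & background
        K = len(members)
        k = len(query & members)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(k_eff, K, n, N)
        rows.append((s.name, k, K, p))
    adj = _bh_adjust([p for _, _, _, p in rows])
    results = [
        EnrichmentResult(name, k, K, n, N, p, p_bh, p < alpha)
        for (name, k, K, p), p_bh in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p, r.name))
    return results


# ---------------------------------------------------------------------------
# File formats

def read_gmt(path, background: Optional[Iterable[str]] = None) -> GeneSetCollection:
    """Read gene sets from GMT (name <tab> description <tab> gene...)."""
    sets = []
    with open(path, newline="") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {ln!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            sets.append(GeneSet(name, desc, frozenset(g for g in genes if g)))
    bg = frozenset(background) if background is not None else None
    return GeneSetCollection(sets, bg)


def write_enrichment(
    results: Sequence[EnrichmentResult], path, header_comment: str = ""
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "k", "K", "n", "N", "p", "p_BH", "significant"])
        for r in results:
            w.writerow(
                [r.name, r.k, r.K, r.n, r.N, f"{r.p:.6g}", f"{r.p_bh:.6g}", int(r.significant)]
            )
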