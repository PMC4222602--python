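"""Gene-set enrichment and literature co-occurrence screening.

Enrichment of a signature inside a target gene set is tested with the exact
hypergeometric upper tail.  Relatedness of two terms in a document corpus is
measured with the Normalized Google Distance (NGD),

    NGD(x, y) = [max(log f(x), log f(y)) - log f(x, y)]
                / [log N - min(log f(x), log f(y))],

computed from supplied occurrence/co-occurrence count tables (no live web
queries): 0 for terms always used together, 1 for statistically independent
terms, infinity for terms that never co-occur.  The formula is a ratio of
logarithm differences, so it is independent of the logarithm base; natural
logs are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats


class SetError(ValueError):
    """Gene sets violate the subset requirements of the test."""


class CorpusError(ValueError):
    """Count-table values are inconsistent with the corpus size."""


@dataclass(frozen=True)
class EnrichmentResult:
    n_target: int
    n_overlap: int
    n_signature: int
    n_background: int
    p_value: float


def hypergeom_enrichment(
    target: Iterable[str], signature: Iterable[str], background: Iterable[str]
) -> EnrichmentResult:
    """Exact hypergeometric over-representation test P(X >= k).

    ``target`` and ``signature`` must both be subsets of ``background``; the
    p-value is the exact upper tail of the hypergeometric distribution for
    the observed overlap k.
    """
    bg = set(background)
    tg = set(target)
    sig = set(signature)
    if not tg <= bg:
        raise SetError("target set is not contained in the background")
    if not sig <= bg:
        raise SetError("signature set is not contained in the background")
    k = len(tg & sig)
    # P(X >= k) = sf(k - 1) for X ~ Hypergeom(M=|bg|, n=|sig|, N=|tg|)
    p = float(stats.hypergeom.sf(k - 1, len(bg), len(sig), len(tg)))
    return EnrichmentResult(
        n_target=len(tg),
        n_overlap=k,
        n_signature=len(sig),
        n_background=len(bg),
        p_value=min(p, 1.0),
    )


def ngd(fx: float, fy: float, fxy: float, n_pages: float) -> float:
    """Normalized Google Distance of two terms from their counts.

    ``fx``/``fy`` are the terms' document counts, ``fxy`` their co-occurrence
    count, ``n_pages`` the corpus size.  Returns infinity when the terms
    never co-occur.
    """
    if fx < 1 or fy < 1:
        raise CorpusError("term counts must be at least 1")
    if n_pages <= max(fx, fy):
        raise CorpusError("corpus size must exceed every term count")
    if fxy > min(fx, fy):
        raise CorpusError("co-occurrences cannot exceed either marginal count")
    if fxy == 0:
        return float("inf")
    lx, ly, lxy = np.log(fx), np.log(fy), np.log(fxy)
    return float((max(lx, ly) - lxy) / (np.log(n_pages) - min(lx, ly)))


def ngd_screen(
    term_counts: Mapping[str, float],
    pair_counts: Mapping[str, float],
    anchor: str,
    n_pages: float,
    threshold: float = 1.0,
) -> set[str]:
    """Terms closer to ``anchor`` than ``threshold`` in NGD (strictly).

    ``pair_counts`` maps term -> co-occurrence count with the anchor; terms
    without an entry are treated as never co-occurring (NGD = infinity).
    The default threshold 1.0 is the NGD of statistically independent terms,
    so the screen keeps terms that co-occur with the anchor more often than
    chance.
    """
    if anchor not in term_counts:
        raise CorpusError(f"anchor term {anchor!r} absent from the count table")
    fa = term_counts[anchor]
    hits = set()
    for term, ft in term_counts.items():
        if term == anchor:
            continue
        d = ngd(fa, ft, pair_counts.get(term, 0.0), n_pages)
        if d < threshold:
            hits.add(term)
    return hits


def independent_cooccurrence(fx: float, fy: float, n_pages: float) -> float:
    """Expected co-occurrence count of independent terms, f(x) f(y) / N."""
    return fx * fy / n_pages
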