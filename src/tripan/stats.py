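"""Enrichment statistics and printed-fraction arithmetic.

Gene-set enrichment is the classic one-sided (over-representation) Fisher
exact test on the 2x2 table (in-set with term, in-set without, out-of-set
with, out-of-set without), with Benjamini-Hochberg control across all tested
terms. Fractions destined for a report are rounded half-up at the cited
precision, matching how percentages are typically printed in manuscripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError, UndefinedFractionError


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int           # genes in set carrying the term
    n: int           # gene-set size
    K: int           # universe genes carrying the term
    N: int           # universe size
    odds_ratio: float
    p: float
    q: float


def fisher_pvalue(k, n, K, N):
    """One-sided (over-representation) Fisher exact p-value.

    Identically the upper hypergeometric tail P(X >= k) for X ~
    Hypergeom(N, K, n); accepts scalars or aligned arrays.
    """
    return hypergeom.sf(np.asarray(k) - 1, N, K, n)


def _sample_odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_annotations: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Per-term over-representation of ``gene_set`` within ``universe``.

    ``term_annotations`` maps gene -> iterable of term labels. Terms absent
    from the universe (K=0) are skipped. Results are sorted by p then term.
    """
    uni = set(universe)
    genes = set(gene_set)
    if not uni:
        raise InputError("empty universe")
    if not genes:
        raise InputError("empty gene set")
    if not genes <= uni:
        raise InputError("gene set is not a subset of the universe")
    term_members: dict[str, set[str]] = {}
    for gene in uni:
        for term in term_annotations.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)
    N, n = len(uni), len(genes)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        if K == 0:
            continue
        k = len(members & genes)
        p = float(fisher_pvalue(k, n, K, N))
        rows.append((term, k, K, _sample_odds_ratio(k, n, K, N), p))
    if not rows:
        return []
    pvals = [r[4] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, odds_ratio=odds,
                         p=p, q=float(q))
        for (t, k, K, odds, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.p, r.term))


def printed_fraction_report(
    entries: Sequence[tuple[str, float, float, int]],
) -> pd.DataFrame:
    """Percentages recomputed from numerator/denominator pairs.

    Each entry is ``(label, numerator, denominator, decimals)``; the output
    carries the percentage rounded half-up at the requested precision.
    """
    rows = []
    for label, num, den, decimals in entries:
        if den == 0:
            raise UndefinedFractionError(f"{label}: zero denominator")
        pct = round_half_up(100.0 * num / den, decimals)
        rows.append(
            {"label": label, "numerator": num, "denominator": den,
             "percent": pct}
        )
    return pd.DataFrame(rows, columns=["label", "numerator", "denominator",
                                       "percent"])
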