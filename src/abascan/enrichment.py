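"""Annotation-term enrichment among candidates versus a background set.

For each term with at least one candidate member the module reports fold
enrichment ``(k/n)/(K/N)`` and the exact one-sided hypergeometric
over-representation p-value, Benjamini–Hochberg adjusted across all tested
terms.  The tail sum is computed exactly in log space (no normal
approximation): at proteome-scale backgrounds this is cheap, and exactness
lets the implementation be checked against brute-force enumeration.

Terms are opaque labels; no ontology-graph propagation is performed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .proteome_io import TableError, _open_read, _open_write

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTable:
    """Term memberships over a background universe of protein ids."""

    terms: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} has no members")
            stray = members - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} has members outside the background: {sorted(stray)[:5]}"
                )


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's counts, fold enrichment, exact p and BH q."""

    term: str
    k: int  # candidates with the term
    n: int  # candidates tested
    K: int  # background members with the term
    N: int  # background size
    fold: float
    p_hyper: float
    q_bh: float


def read_annotation_tsv(source, background: Iterable[str] | None = None) -> AnnotationTable:
    """Read a long-format ``term<TAB>seq_id`` annotation TSV.

    ``background`` defaults to the union of all annotated ids; pass the
    scanned proteome's ids to use it as the universe instead.
    """
    terms: dict[str, set[str]] = {}
    with _open_read(source) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise TableError(f"line {lineno}: expected 'term<TAB>seq_id'")
            term, seq_id = row[0].strip(), row[1].strip()
            if lineno == 1 and (term, seq_id) == ("term", "seq_id"):
                continue  # optional header
            terms.setdefault(term, set()).add(seq_id)
    if background is None:
        bg = frozenset().union(*terms.values()) if terms else frozenset()
    else:
        bg = frozenset(background)
    return AnnotationTable({t: frozenset(m) for t, m in terms.items()}, bg)


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Fold enrichment ``(k/n)/(K/N)``; 0 when k = 0."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 0.0
    if K == 0:
        raise ValueError("K = 0 with k > 0 is inconsistent")
    return (k / n) / (K / N)


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if n <= 0 or N <= 0:
        raise ValueError("n and N must be positive")
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")


def _log_comb(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space with log-gamma binomial coefficients; returns a
    value in (0, 1] and P(X >= 0) = 1 exactly.
    """
    _check_counts(k, n, K, N)
    lo = max(0, n + K - N)  # smallest attainable overlap
    if k <= lo:
        return 1.0
    hi = min(n, K)
    xs = np.arange(k, hi + 1)
    if xs.size == 0:
        return 0.0
    log_terms = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    ps = list(p_values)
    if not ps:
        return []
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(v) for v in q]


def enrich(
    candidates: Iterable[str],
    annotations: AnnotationTable,
    q_threshold: float = 0.05,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Test every term with >=1 candidate member for over-representation.

    Returns ``(all_results, retained)``: all tested terms sorted by
    (p, term), and the subset surviving BH-FDR at ``q_threshold``.
    Candidate ids outside the background are dropped with a logged warning.
    """
    if not annotations.background:
        raise ValueError("empty annotation background")
    cand = set(candidates)
    stray = cand - annotations.background
    if stray:
        logger.warning(
            "dropping %d candidate id(s) not in the background: %s",
            len(stray), sorted(stray)[:5],
        )
        cand -= stray
    n = len(cand)
    N = len(annotations.background)
    tested: list[tuple[str, int, int]] = []
    for term, members in annotations.terms.items():
        k = len(cand & members)
        if k >= 1:
            tested.append((term, k, len(members)))
    ps = [hypergeom_tail(k, n, K, N) for _, k, K in tested]
    qs = bh_adjust(ps)
    results = [
        EnrichmentResult(
            term=term, k=k, n=n, K=K, N=N,
            fold=fold_enrichment(k, n, K, N),
            p_hyper=p, q_bh=q,
        )
        for (term, k, K), p, q in zip(tested, ps, qs)
    ]
    results.sort(key=lambda r: (r.p_hyper, r.term))
    retained = [r for r in results if r.q_bh < q_threshold]
    return results, retained


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], dest, q_threshold: float = 0.05
) -> None:
    """Write results as ``term k n K N fold p q retained`` TSV."""
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term", "k", "n", "K", "N", "fold", "p", "q", "retained"])
        for r in results:
            writer.writerow(
                [r.term, r.k, r.n, r.K, r.N, f"{r.fold:.6g}",
                 f"{r.p_hyper:.6g}", f"{r.q_bh:.6g}", int(r.q_bh < q_threshold)]
            )
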