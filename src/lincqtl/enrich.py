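"""Hypergeometric over-representation test of a gene set against flat term
annotations, with Benjamini-Hochberg correction across tested terms.

This is the generic stand-in for a GO/KEGG enrichment stage: given a
target set of n genes from a background of N, a term annotating K
background genes of which k are targets has upper-tail p-value
P(X >= k) with X ~ Hypergeometric(N, K, n).  No ontology-graph
propagation is performed; terms are flat gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple, Union

from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .models import ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # targets annotated to the term
    K: int  # background genes annotated to the term
    n: int  # target set size
    N: int  # background size
    p_value: float
    q_value: float
    fold_enrichment: float


def _term_genes(entry) -> Tuple[str, frozenset]:
    if isinstance(entry, tuple):
        name, genes = entry
        return name, frozenset(genes)
    return "", frozenset(entry)


def hypergeom_enrich(
    targets: Iterable[str],
    term_map: Mapping[str, Union[Tuple[str, Iterable[str]], Iterable[str]]],
    background: Optional[Iterable[str]] = None,
) -> List[EnrichmentResult]:
    """Test each term for over-representation among the target genes.

    ``term_map`` maps term id to either a gene set or a (name, gene set)
    tuple.  ``background`` defaults to all genes with at least one term
    annotation; every target must belong to it.  Terms with no background
    gene are skipped.  Results are sorted by ascending p-value (ties by
    term id).
    """
    terms: Dict[str, Tuple[str, frozenset]] = {
        t: _term_genes(entry) for t, entry in term_map.items()
    }
    if background is None:
        bg: Set[str] = set()
        for _, genes in terms.values():
            bg |= genes
    else:
        bg = set(background)
    target_set = set(targets)
    strays = sorted(target_set - bg)
    if strays:
        raise ValidationError(
            f"{len(strays)} target genes absent from background: "
            + ", ".join(strays[:10])
            + ("..." if len(strays) > 10 else "")
        )
    N, n = len(bg), len(target_set)
    tested = []
    for term_id in sorted(terms):
        name, genes = terms[term_id]
        term_bg = genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & target_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fe = (k / n) / (K / N) if n > 0 else 0.0
        tested.append((term_id, name, k, K, p, fe))
    qvals = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term_id=tid, term_name=name, k=k, K=K, n=n, N=N,
            p_value=p, q_value=float(q), fold_enrichment=fe,
        )
        for (tid, name, k, K, p, fe), q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
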