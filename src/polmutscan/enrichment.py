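"""Generic term enrichment for gene sets (GO/KEGG-style).

For each term with K carriers among N universe genes, the probability of
seeing at least k carriers in a study set of n genes drawn without
replacement is the hypergeometric upper tail P(X >= k); p-values are
BH-adjusted across all terms tested in a batch.  No term-hierarchy
propagation is applied — the term map is taken as given.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .expression import bh_adjust
from .models import EnrichmentResult, ModelError


def hypergeom_enrich(
    study_set: Iterable[str],
    term_map: Mapping[str, set[str]],
    universe: Iterable[str],
    direction: str = "",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of `study_set` against `universe`.

    Term gene sets are intersected with the universe first; terms with no
    study-set carriers are skipped.  Results are sorted by p-value.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ModelError("empty universe")
    study = set(study_set)
    outside = study - universe_set
    if outside:
        raise ModelError(
            f"study genes outside universe: {sorted(outside)[:5]}"
            + ("..." if len(outside) > 5 else "")
        )
    N, n = len(universe_set), len(study)
    results: list[EnrichmentResult] = []
    for term, genes in term_map.items():
        carriers = genes & universe_set
        K = len(carriers)
        k = len(carriers & study)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(term_id=term, k=k, n=n, K=K, N=N, p=p, direction=direction)
        )
    if results:
        fdrs = bh_adjust([r.p for r in results])
        for r, f in zip(results, fdrs):
            r.fdr = f
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
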