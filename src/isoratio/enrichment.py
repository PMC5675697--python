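"""Gene-ontology-style over-representation testing.

Terms are tested with the one-sided hypergeometric upper tail (the Fisher
exact test for enrichment) against the analysis universe — the background of
genes that entered the statistical testing, not the genome.  To reduce the
redundancy induced by parent-child term relations, the published *elim*
scheme is available: terms are visited children-before-parents and the genes
of a term found significant at ``alpha`` are eliminated from its ancestors'
annotation before those are tested.  No multiple-testing correction is
applied across terms (raw over-representation p-values are reported).
"""

from __future__ import annotations

from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

DEFAULT_MIN_HITS = 5


def _term_to_genes(annotations: dict[str, set[str]], universe: set[str]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            out.setdefault(t, set()).add(gene)
    return out


def hypergeom_upper_tail(hits: int, universe: int, annotated: int, set_size: int) -> float:
    """P(X >= hits) for X ~ Hypergeom(universe, annotated, set_size)."""
    return float(stats.hypergeom.sf(hits - 1, universe, annotated, set_size))


def fisher_enrich(
    gene_set,
    universe,
    annotations: dict[str, set[str]],
    min_hits: int = DEFAULT_MIN_HITS,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``gene_set`` must be a subset of ``universe``.  Terms with zero annotated
    genes in the universe are skipped; the report keeps terms with at least
    ``min_hits`` genes from the set (pass ``min_hits=0`` for everything).
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[0]
        raise ValidationError(f"gene {extra!r} in the set but not in the universe")
    term_genes = _term_to_genes(annotations, universe)
    n_u, n_s = len(universe), len(gene_set)
    rows = []
    for term in sorted(term_genes):
        ann = term_genes[term]
        if not ann:
            continue
        members = sorted(ann & gene_set)
        hits = len(members)
        p = hypergeom_upper_tail(hits, n_u, len(ann), n_s)
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "annotated_in_universe": len(ann),
                "significant_in_set": hits,
                "expected": n_s * len(ann) / n_u,
                "p_value": p,
                "member_genes": ";".join(members),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "annotated_in_universe",
                                      "significant_in_set", "expected", "p_value", "member_genes"])
    out = out.loc[out["significant_in_set"] >= min_hits].reset_index(drop=True)
    return out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)


def _ancestors(edges: list[tuple[str, str]]) -> dict[str, set[str]]:
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    anc: dict[str, set[str]] = {}

    def walk(term: str) -> set[str]:
        if term in anc:
            return anc[term]
        acc: set[str] = set()
        for p in parents.get(term, ()):  # noqa: B007
            acc.add(p)
            acc |= walk(p)
        anc[term] = acc
        return acc

    for t in list(parents):
        walk(t)
    return anc


def elim_decorrelate(
    gene_set,
    universe,
    annotations: dict[str, set[str]],
    dag_edges: list[tuple[str, str]],
    alpha: float = 0.05,
    min_hits: int = 0,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Bottom-up elim over-representation testing on a term DAG.

    ``dag_edges`` is a (child, parent) list.  Terms are tested leaves-first;
    when a term is significant at ``alpha`` its (currently effective) genes
    are removed from every ancestor's annotation before the ancestor is
    tested.  A flat DAG (no edges) reduces to :func:`fisher_enrich`.
    Cyclic input is rejected.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[0]
        raise ValidationError(f"gene {extra!r} in the set but not in the universe")
    term_genes = _term_to_genes(annotations, universe)
    # topological order with children before parents: child -> parent edges
    ts = TopologicalSorter({t: set() for t in term_genes})
    for child, parent in dag_edges:
        ts.add(parent, child)  # parent depends on child
    try:
        order = list(ts.static_order())
    except CycleError as err:
        raise ValidationError("ontology DAG contains a cycle") from err
    ancestors = _ancestors(dag_edges)
    eliminated: dict[str, set[str]] = {t: set() for t in term_genes}
    n_u, n_s = len(universe), len(gene_set)
    rows = []
    for term in order:
        if term not in term_genes:
            continue
        eff = term_genes[term] - eliminated.get(term, set())
        members = sorted(eff & gene_set)
        hits = len(members)
        p = hypergeom_upper_tail(hits, n_u, len(eff), n_s) if eff else 1.0
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "annotated_in_universe": len(eff),
                "significant_in_set": hits,
                "expected": n_s * len(eff) / n_u,
                "p_value": p,
                "member_genes": ";".join(members),
            }
        )
        if p <= alpha:
            for anc in ancestors.get(term, ()):  # remove this term's genes upstream
                eliminated.setdefault(anc, set()).update(eff)
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "annotated_in_universe",
                                      "significant_in_set", "expected", "p_value", "member_genes"])
    out = out.loc[out["significant_in_set"] >= min_hits].reset_index(drop=True)
    return out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
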