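"""Gene-set over-representation analysis for age-position gene lists.

Each age-position's member genes are tested for enrichment in user-supplied
gene sets (GMT) with a one-sided Fisher's exact test against a stated
background, after discarding overly generic (> 1000 genes) and overly
specific (< 10 genes) sets. Optional Benjamini-Hochberg correction yields
q-values. Significant ontology terms can be grouped into functional
families by shared non-root ancestry in an OBO is_a DAG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import obonet
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "read_obo",
    "fisher_enrichment",
    "enrich_collection",
    "group_terms",
    "collapse_probes_to_genes",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file."""

    sets: dict  # term id -> (name, frozenset of gene ids)
    source: str = ""

    def __len__(self):
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """One term's 2x2 over-representation table and test outcome.

    a = list genes in the set, b = list genes outside it, c = non-list
    genes in the set, d = the remainder of the background.
    """

    term_id: str
    term_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None
    group_id: str | None = None


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file (term, description, member genes...)."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {ln}: fewer than 3 fields")
            term, name, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if term in sets:
                raise ValueError(f"duplicate term id {term!r} at GMT line {ln}")
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"GMT line {ln} ({term}): duplicate genes deduplicated",
                    stacklevel=2,
                )
            if not genes:
                raise ValueError(f"empty gene set at GMT line {ln}")
            sets[term] = (name, frozenset(genes))
    return GeneSetCollection(sets=sets, source=str(path))


def read_obo(path) -> nx.DiGraph:
    """Parse an OBO ontology into a child -> parent is_a DAG."""
    multigraph = obonet.read_obo(path)
    dag = nx.DiGraph()
    dag.add_nodes_from(multigraph.nodes(data=True))
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology is_a relations contain a cycle")
    return dag


def collapse_probes_to_genes(probe_ids, gene_map: dict) -> set:
    """Unique gene ids for a probe list; a gene is in if any of its probes is."""
    return {gene_map[p] for p in probe_ids if p in gene_map}


def fisher_enrichment(list_genes, term_genes, background_genes,
                      term_id: str = "", term_name: str = "") -> EnrichmentResult:
    """One-sided Fisher's exact test for over-representation of one term.

    The term is intersected with the background first; p is the upper
    hypergeometric tail P(overlap >= a) given the margins. The odds ratio is
    (a*d)/(b*c), infinite when b*c = 0.
    """
    background = set(background_genes)
    lst = set(list_genes)
    if not background or not lst:
        raise ValueError("background and gene list must be non-empty")
    if not lst <= background:
        raise ValueError("gene list must be a subset of the background")
    term = set(term_genes) & background
    a = len(lst & term)
    b = len(lst - term)
    c = len(term - lst)
    d = len(background) - a - b - c
    n = len(background)
    # upper tail of Hypergeometric(N=n, K=|term|, draws=|list|) at a
    p = float(stats.hypergeom.sf(a - 1, n, a + c, a + b))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    return EnrichmentResult(
        term_id=term_id, term_name=term_name, a=a, b=b, c=c, d=d,
        odds_ratio=odds, p_value=p,
    )


def enrich_collection(
    list_genes,
    collection: GeneSetCollection,
    background_genes,
    min_size: int = 10,
    max_size: int = 1000,
    alpha: float = 0.05,
    fdr: bool = False,
):
    """Test every admissible gene set and flag the significant ones.

    Size filters apply to the term-within-background size (inclusive bounds
    after excluding < min_size and > max_size, per the generic/specific-term
    rule). Exact-duplicate member sets are collapsed to the lexicographically
    first term id. With ``fdr=True``, Benjamini-Hochberg q-values are added
    and significance uses q < alpha; otherwise raw p < alpha.

    Returns ``(results_sorted_by_p, significant_results)``.
    """
    background = set(background_genes)
    seen_membersets = {}
    admissible = []
    for term in sorted(collection.sets):
        name, genes = collection.sets[term]
        members = frozenset(genes & background)
        size = len(members)
        if size < min_size or size > max_size:
            continue
        if members in seen_membersets:
            logger.info(
                "term %s duplicates %s; dropped", term, seen_membersets[members]
            )
            continue
        seen_membersets[members] = term
        admissible.append((term, name, members))

    results = [
        fisher_enrichment(list_genes, members, background, term_id=term,
                          term_name=name)
        for term, name, members in admissible
    ]
    if fdr and results:
        pvals = [r.p_value for r in results]
        _, qvals, *_ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if fdr:
        significant = [r for r in results if r.q_value < alpha]
    else:
        significant = [r for r in results if r.p_value < alpha]
    return results, significant


def _ancestors_or_self(dag: nx.DiGraph, node) -> set:
    # edges point child -> parent, so ancestors are nx descendants
    return {node} | nx.descendants(dag, node)


def group_terms(term_ids, dag: nx.DiGraph) -> dict:
    """Group significant terms into functional families by shared ancestry.

    Two terms belong to the same group when they share at least one common
    non-root ancestor (a term counts as its own ancestor, so a term and its
    parent group together). Roots — nodes with no is_a parent — are too
    generic to carry functional kinship and are excluded. Terms absent from
    the DAG form singleton groups (logged). Group labels are the
    lexicographically smallest member term id.
    """
    term_ids = list(term_ids)
    roots = {n for n in dag.nodes if dag.out_degree(n) == 0}
    present = [t for t in term_ids if t in dag]
    for t in term_ids:
        if t not in dag:
            logger.info("term %s absent from ontology; singleton group", t)

    anc = {t: (_ancestors_or_self(dag, t) - roots) for t in present}
    g = nx.Graph()
    g.add_nodes_from(term_ids)
    for i, u in enumerate(present):
        for v in present[i + 1:]:
            if anc[u] & anc[v]:
                g.add_edge(u, v)
    groups = {}
    for component in nx.connected_components(g):
        label = min(component)
        for t in component:
            groups[t] = label
    return groups
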