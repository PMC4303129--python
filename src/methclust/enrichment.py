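"""Gene-set over-representation analysis against the array's gene background.

A flat hypergeometric over-representation test per annotation term, with
BH FDR across terms — a desk-scale replacement for web-service annotation
tools.  Probes map to genes through the manifest, genes with multiple CpG
probes count once, terms are intersected with the background universe
before testing, and an optional EASE-style conservative variant
(overlap − 1 in the tail) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .containers import ProbeManifest
from .differential import bh_fdr

__all__ = ["GeneSetAnnotation", "read_gmt", "write_gmt", "dedupe_genes", "enrich"]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetAnnotation:
    """One annotation term and its member genes."""

    term_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(self.genes)


def read_gmt(path) -> list[GeneSetAnnotation]:
    """Parse a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    terms = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            terms.append(GeneSetAnnotation(parts[0], parts[1], frozenset(filter(None, parts[2:]))))
    return terms


def write_gmt(terms, path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")


def dedupe_genes(probes, manifest: ProbeManifest) -> list[str]:
    """Unique gene symbols for a probe list (genes with several CpGs count once).

    Order of first appearance is preserved.
    """
    if len(list(probes)) == 0:
        return []
    genes = manifest.genes_for(list(probes))
    return list(dict.fromkeys(genes))


def enrich(
    gene_list,
    annotation: list[GeneSetAnnotation],
    background,
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation p per term, BH q across terms.

    For a background of N genes, a term with K members in the background
    and a query list of n genes overlapping the term in k, the p-value is
    the upper hypergeometric tail P(X >= k).  ``ease=True`` uses the more
    conservative P(X >= k-1 | k>0) style tail (overlap decremented by one).
    Terms disjoint from the background are skipped with a log entry.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(gene_list)
    if not query <= background:
        raise ValueError("gene_list must be a subset of the background")
    N, n = len(background), len(query)
    rows = []
    for term in annotation:
        members = term.genes & background
        if not members:
            logger.info("term %s disjoint from background; skipped", term.term_id)
            continue
        K = len(members)
        k = len(query & members)
        k_eff = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "overlap": k,
                "list_size": n,
                "background_size": N,
                "term_size": K,
                "raw_p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["raw_p"].to_numpy())
        out["significant"] = out["q"] < alpha
        out = out.sort_values(["q", "raw_p", "term_id"], kind="stable").reset_index(drop=True)
    return out
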