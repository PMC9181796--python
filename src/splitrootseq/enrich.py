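"""Hypergeometric over-representation of annotation terms in gene sets.

For a gene set of size n drawn from a background of N genes, a term
annotating K background genes and overlapping the set in k genes gets the
upper-tail probability p = P(X >= k), X ~ Hypergeometric(N, K, n), i.e. the
chance of an overlap at least this large under sampling without
replacement. p-values are Benjamini-Hochberg adjusted within each
annotation category (BP/MF/CC/pathway); terms with FDR <= 0.05 are called
enriched. Over-representation only — depletion is not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_ENRICH_FDR = 0.05


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str = ""
    category: str = "BP"
    genes: frozenset = field(default_factory=frozenset)


def read_gmt(path: str | Path, category: str = "BP") -> list[TermAnnotation]:
    """Read term annotations from a GMT file (term, description, members...)."""
    terms: list[TermAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: term {fields[0]!r} has no members")
            terms.append(
                TermAnnotation(
                    term_id=fields[0], term_name=fields[1], category=category,
                    genes=members,
                )
            )
    return terms


def read_gene_term_tsv(path: str | Path, category: str = "BP") -> list[TermAnnotation]:
    """Read two-column (gene, term) TSV annotations."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    terms = []
    for term, grp in df.groupby("term", sort=True):
        terms.append(
            TermAnnotation(
                term_id=str(term), term_name=str(term), category=category,
                genes=frozenset(grp["gene"]),
            )
        )
    return terms


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent hypergeometric instance k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    gene_set: set | frozenset,
    background: set | frozenset,
    annotations: list[TermAnnotation],
    fdr_max: float = DEFAULT_ENRICH_FDR,
) -> pd.DataFrame:
    """Over-representation of each annotated term in `gene_set`.

    The annotation file defines the testable universe: term members outside
    `background` are dropped (logged), and BH adjustment runs within each
    category. Raises if the gene set is not a subset of the background.
    """
    gene_set = frozenset(gene_set)
    background = frozenset(background)
    stray = gene_set - background
    if stray:
        raise ValueError(
            f"gene set contains {len(stray)} gene(s) absent from background, "
            f"e.g. {sorted(stray)[:5]}"
        )
    N, n = len(background), len(gene_set)
    rows = []
    for t in annotations:
        members = t.genes & background
        dropped = len(t.genes) - len(members)
        if dropped:
            log.warning("term %s: dropped %d gene(s) outside background", t.term_id, dropped)
        if not members:
            continue
        k = len(members & gene_set)
        rows.append(
            {
                "term_id": t.term_id, "term_name": t.term_name,
                "category": t.category, "k": k, "K": len(members), "n": n, "N": N,
                "p": hypergeom_pvalue(k, len(members), n, N),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p"]
    )
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
        return df
    df["fdr"] = 1.0
    for _, idx in df.groupby("category").groups.items():
        df.loc[idx, "fdr"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df["enriched"] = df["fdr"] <= fdr_max
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def top_terms(records: pd.DataFrame, count: int) -> pd.DataFrame:
    """The `count` terms with the smallest p; ties broken by term_id."""
    return (
        records.sort_values(["p", "term_id"], kind="mergesort")
        .head(count)
        .reset_index(drop=True)
    )


def direction_score(up_count: int, down_count: int, total_count: int) -> float:
    """(up - down) / total: net direction of a DEG set, in [-1, 1]."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if up_count < 0 or down_count < 0 or up_count + down_count > total_count:
        raise ValueError("require 0 <= up + down <= total")
    return (up_count - down_count) / total_count


def term_gene_edges(
    records: pd.DataFrame,
    gene_set: set | frozenset,
    annotations: list[TermAnnotation],
    enriched_only: bool = True,
) -> pd.DataFrame:
    """(term, gene) edge list for enriched terms, for network consumers."""
    keep = set(records.loc[records["enriched"], "term_id"] if enriched_only else records["term_id"])
    rows = [
        {"term_id": t.term_id, "gene_id": g}
        for t in annotations
        if t.term_id in keep
        for g in sorted(t.genes & frozenset(gene_set))
    ]
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])
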