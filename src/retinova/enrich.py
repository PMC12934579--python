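"""Gene-set over-representation and cell-type percent enrichment.

Over-representation analysis (ORA) tests whether a query gene set (e.g.
module hub genes) overlaps a named gene set more than expected under
hypergeometric sampling from a gene universe, with BH FDR across sets.
Cell-type enrichment summarizes what fraction of a module's hub genes are
unique markers of each retinal cell type or neurovascular-unit (NVU)
class, using marker sets built from a single-cell atlas table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora",
    "hub_genes",
    "unique_markers",
    "percent_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("set names must be unique")
        # harmonize: members outside the universe are dropped
        self.sets = {name: set(g) & self.universe for name, g in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: set | None = None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> genes...)."""
    sets: dict[str, set] = {}
    genes_seen: set = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = parts
        sets[name] = set(m for m in members if m)
        genes_seen |= sets[name]
    return GeneSetCollection(sets, universe if universe is not None else genes_seen)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ora(
    query: set,
    collection: GeneSetCollection,
    padj_max: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p is the upper-tail probability of drawing at least the observed
    overlap when |query| genes are sampled from the universe without
    replacement. BH adjustment runs across all sets; ``significant`` marks
    padj < padj_max with overlap >= min_overlap (the minimum-count filter
    used when reporting term associations).
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty gene universe")
    dropped = set(query) - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe were dropped")
    q = set(query) & universe
    m_univ = len(universe)
    rows = []
    for name, members in collection.sets.items():
        k = len(q & members)
        # P(X >= k), X ~ Hypergeom(M=universe, n=set size, N=query size)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(members), len(q)))
        rows.append((name, k, len(members), len(q), m_univ, p, sorted(q & members)))
    out = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "query_size", "universe_size", "pvalue", "genes"],
    ).set_index("set")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = (out["padj"] < padj_max) & (out["overlap"] >= min_overlap)
    return out.sort_values("pvalue")


def hub_genes(kme_table: pd.DataFrame, labels: pd.Series, module: str, kme_min: float = 0.7) -> set:
    """Genes assigned to ``module`` with own-module kME strictly above ``kme_min``.

    The convention follows the hub-gene thresholds used for module
    characterization (kME > 0.6 for GO analysis, kME > 0.7 for cell-type
    enrichment); equality is excluded.
    """
    if module not in kme_table.columns:
        raise ValueError(f"unknown module {module!r}")
    members = labels.index[labels == module]
    vals = kme_table.loc[kme_table.index.intersection(members), module]
    return set(vals.index[vals > kme_min])


def unique_markers(
    table: pd.DataFrame,
    lfc_min: float = 0.25,
    padj_max: float = 0.05,
    top_k: int = 1000,
) -> GeneSetCollection:
    """Unique-within-class marker sets from an atlas table.

    Per class: keep rows with log2FC > lfc_min (strict) and padj < padj_max
    (strict); rank by log2FC descending (ties broken by ascending padj,
    then gene ID) and keep the top ``top_k``; finally drop every gene that
    survives in more than one class, so the sets are pairwise disjoint.
    ``top_k`` is 1000 for major cell types and 2000 for broad NVU classes.
    """
    required = {"gene", "class", "log2FC", "padj"}
    if not required <= set(table.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    kept: dict[str, list[str]] = {}
    for cls, sub in table.groupby("class"):
        sig = sub[(sub["log2FC"] > lfc_min) & (sub["padj"] < padj_max)]
        sig = sig.sort_values(
            ["log2FC", "padj", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        kept[cls] = list(sig["gene"].head(top_k))
    counts: dict[str, int] = {}
    for genes in kept.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    sets = {cls: {g for g in genes if counts[g] == 1} for cls, genes in kept.items()}
    universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, universe)


def percent_enrichment(hub: set, collection: GeneSetCollection) -> pd.Series:
    """Percent of hub genes that are markers of each class.

    For each class set S: 100 * |hub & S| / |hub|. With pairwise-disjoint
    marker sets the percentages sum to at most 100.
    """
    if not hub:
        raise ValueError("hub gene set is empty")
    n = len(hub)
    vals = {name: 100.0 * len(hub & members) / n for name, members in collection.sets.items()}
    return pd.Series(vals, name="percent_enrichment").sort_values(ascending=False)
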