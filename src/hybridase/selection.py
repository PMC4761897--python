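"""Directional allelic selection sets and gene-set enrichment.

An allele from one parental background that is significantly over-
expressed (or under-expressed) relative to its partner in *all three*
hybrids carrying that parent is a candidate for directional selection
on its cis-regulation: the same haplotype wins (or loses) against three
different competitors.  Per parent strain this yields a maximally- and
a minimally-expressed gene set, which are then tested for functional
enrichment against user-supplied gene sets (GMT) with a one-sided
hypergeometric test and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ase_quant import bh_adjust

DEFAULT_Q = 0.05
DEFAULT_ENRICH_FDR = 0.10


@dataclass
class DirectionalSet:
    """Per-parent maximally/minimally expressed allele sets with support."""

    parent: str
    max_expressed: set[str] = field(default_factory=set)
    min_expressed: set[str] = field(default_factory=set)
    support: pd.DataFrame | None = None  # (gene, hybrid, M_parent, q)


def _orient(ase: pd.DataFrame, parent: str) -> pd.DataFrame:
    """Rows of the ASE table involving ``parent``, with M oriented so that
    positive favours the parent's allele."""
    hit1 = ase["allele1"] == parent
    hit2 = ase["allele2"] == parent
    sub = ase[hit1 | hit2].copy()
    sub["M_parent"] = np.where(sub["allele1"] == parent, sub["M"], -sub["M"])
    return sub


def directional_sets(ase: pd.DataFrame, parent: str,
                     q_threshold: float = DEFAULT_Q) -> DirectionalSet:
    """Alleles of ``parent`` significant with a consistent sign in all
    three of its hybrids.

    A gene joins ``max_expressed`` iff in every one of the parent's
    three hybrids it is universally detectable, q < threshold and the
    parent-oriented M > 0; ``min_expressed`` is symmetric with M < 0.
    """
    sub = _orient(ase, parent)
    hybrids = sorted(sub["hybrid"].unique())
    if len(hybrids) != 3:
        raise ValueError(f"parent {parent} appears in {len(hybrids)} hybrids, expected 3")
    sub = sub[sub["uda"]]
    ok = sub[(sub["q"] < q_threshold)]
    out = DirectionalSet(parent=parent)
    counts = ok.groupby("gene").agg(n=("hybrid", "nunique"),
                                    n_pos=("M_parent", lambda m: int((m > 0).sum())),
                                    n_neg=("M_parent", lambda m: int((m < 0).sum())))
    out.max_expressed = set(counts.index[(counts["n"] == 3) & (counts["n_pos"] == 3)])
    out.min_expressed = set(counts.index[(counts["n"] == 3) & (counts["n_neg"] == 3)])
    members = out.max_expressed | out.min_expressed
    out.support = (sub[sub["gene"].isin(members)]
                   [["gene", "hybrid", "M_parent", "q"]]
                   .sort_values(["gene", "hybrid"]).reset_index(drop=True))
    return out


def enrich(gene_set: set[str], universe: set[str], collections: dict[str, set[str]],
           fdr: float = DEFAULT_ENRICH_FDR) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in each category.

    Categories are intersected with the universe; p is the upper tail
    P(X >= overlap) of Hypergeom(|universe|, |category|, |set|); fold is
    the overlap fraction over the category's universe fraction.  Rows
    with BH q < ``fdr`` are flagged.
    """
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & set(universe)
    n_u, n_s = len(universe), len(gene_set)
    rows = []
    for name, members in collections.items():
        cat = set(members) & set(universe)
        k = len(gene_set & cat)
        if not cat:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_u, len(cat), n_s))
        fold = (k / n_s) / (len(cat) / n_u) if n_s else np.nan
        rows.append({"set_name": name, "overlap": k, "set_size": n_s,
                     "category_size": len(cat), "universe": n_u,
                     "fold": fold, "p": p})
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                     "category_size", "universe", "fold", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < fdr
        df = df.sort_values("p").reset_index(drop=True)
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> genes..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(collections: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collections):
            genes = "\t".join(sorted(collections[name]))
            fh.write(f"{name}\t-\t{genes}\n")
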