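"""Hypergeometric over-representation analysis of gene lists."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arraymodel import ConfigError, FormatError

__all__ = ["TermMap", "ora", "read_terms"]


@dataclass(frozen=True)
class TermMap:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"term {self.term_id!r} has empty membership")


def read_terms(path: str | Path) -> list[TermMap]:
    """Read a term->gene membership TSV (term_id, term_name, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for (tid, tname), sub in df.groupby(["term_id", "term_name"], sort=True):
        out.append(TermMap(tid, tname, frozenset(sub["gene_id"])))
    return out


def ora(
    gene_list: Iterable[str],
    universe: Iterable[str],
    term_map: Sequence[TermMap],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` per term.

    Term membership is clipped to the universe; p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  Terms with no overlap are reported with p = 1.
    BH q-values are computed across all tested terms.
    """
    universe = set(universe)
    if not universe:
        raise ConfigError("empty universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ConfigError("gene list contains ids outside the universe")
    N, n = len(universe), len(genes)
    rows = []
    for term in term_map:
        members = term.genes & universe
        if not members:
            continue
        K = len(members)
        k = len(members & genes)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(members & genes)),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p", "genes"]
    )
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
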