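"""Local over-representation analysis: upper-tail hypergeometric test of a
query gene set against GMT collections, with Benjamini-Hochberg FDR."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


class GMTError(ValueError):
    """A GMT file violates the name<TAB>description<TAB>genes... dialect."""


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: genes}`` with dedup; duplicate
    set names and short lines are errors."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise GMTError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = set(fields[2:])
            n_lines += 1
    if n_lines == 0:
        raise GMTError(f"{path}: no gene sets")
    return sets


def ora_test(
    query: set[str], gene_set: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of query/gene-set overlap.

    Returns (k, p) with k = |query ∩ gene_set| and
    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|gene_set ∩ universe|,
    n=|query|).
    """
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    gs = gene_set & universe
    k = len(query & gs)
    n_universe, n_set, n_query = len(universe), len(gs), len(query)
    # sf(k-1) = P(X >= k)
    p = float(hypergeom.sf(k - 1, n_universe, n_set, n_query))
    return k, min(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotone from the top
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class EnrichmentTable:
    """Per-set ORA results sorted by p ascending."""

    frame: pd.DataFrame
    fdr_threshold: float

    def write_tsv(self, path) -> None:
        frame = self.frame.copy()
        frame["neg_log10_p"] = -np.log10(frame["p"])
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def enrich(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.05,
) -> EnrichmentTable:
    """ORA of the query against every set in the collection; all rows kept,
    flagged significant where BH FDR < threshold."""
    if not collection:
        raise ValueError("gene-set collection is empty")
    rows = []
    for name in sorted(collection):
        gs = collection[name] & universe
        k, p = ora_test(query, gs, universe)
        rows.append(
            {
                "gene_set": name,
                "set_size": len(gs),
                "query_size": len(query),
                "universe_size": len(universe),
                "overlap": k,
                "p": p,
            }
        )
    frame = pd.DataFrame(rows)
    frame["fdr"] = bh_fdr(frame["p"].to_numpy())
    frame["significant"] = frame["fdr"] < fdr_threshold
    frame = frame.sort_values(
        ["p", "gene_set"], kind="stable", ignore_index=True
    )
    n_sig = int(frame["significant"].sum())
    logger.info("%d of %d gene sets significant at FDR < %g",
                n_sig, len(frame), fdr_threshold)
    return EnrichmentTable(frame, fdr_threshold)
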