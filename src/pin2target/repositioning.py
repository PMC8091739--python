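"""Overlap-based drug repositioning: rank drugs by how many of their known
targets fall inside the putative-target set. A drug qualifies as a
repositioning candidate if the overlap is non-empty."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from pin2target.pin_data import DrugTargetMap

logger = logging.getLogger(__name__)


@dataclass
class RepositioningRow:
    drug: str
    overlap_genes: list[str]  # sorted
    n_overlap: int
    rank: int


@dataclass
class RepositioningTable:
    """Candidate drugs sorted by overlap count descending, ties broken
    alphabetically by drug name. Only drugs with >=1 overlapping gene."""

    rows: list[RepositioningRow]

    def __len__(self) -> int:
        return len(self.rows)

    def counts(self) -> dict[str, int]:
        return {r.drug: r.n_overlap for r in self.rows}


def infer_candidates(
    drug_map: DrugTargetMap,
    putative: set[str],
    exclude_drugs: set[str] | None = None,
) -> RepositioningTable:
    """Intersect each drug's known targets with the putative gene set.

    ``exclude_drugs`` optionally removes drugs already indicated for the
    query disease; by default nothing is filtered.
    """
    if len(drug_map) == 0:
        raise ValueError("drug-target map is empty")
    if not putative:
        logger.warning("putative target set is empty; no candidates")
        return RepositioningTable([])
    exclude_drugs = exclude_drugs or set()
    hits = []
    for drug in drug_map.drugs:
        if drug in exclude_drugs:
            continue
        overlap = sorted(drug_map.targets[drug] & putative)
        if overlap:
            hits.append((drug, overlap))
    hits.sort(key=lambda h: (-len(h[1]), h[0]))
    rows = [
        RepositioningRow(drug, overlap, len(overlap), rank)
        for rank, (drug, overlap) in enumerate(hits, start=1)
    ]
    logger.info("%d candidate repositionable drugs", len(rows))
    return RepositioningTable(rows)


def write_repositioning_report(table: RepositioningTable, path: str | Path) -> None:
    """TSV: drug, semicolon-joined overlap genes, overlap count, rank."""
    if not table.rows:
        raise ValueError("refusing to write an empty repositioning table")
    with open(path, "w") as fh:
        fh.write("drug\toverlap_genes\tn_overlap\trank\n")
        for r in table.rows:
            fh.write(f"{r.drug}\t{';'.join(r.overlap_genes)}\t{r.n_overlap}\t{r.rank}\n")


def read_repositioning_report(path: str | Path) -> RepositioningTable:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("drug\t"):
            raise ValueError(f"{path}: unexpected header")
        for line in fh:
            drug, genes, n, rank = line.rstrip("\n").split("\t")
            rows.append(RepositioningRow(drug, genes.split(";"), int(n), int(rank)))
    return RepositioningTable(rows)
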