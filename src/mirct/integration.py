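"""miRNA-mRNA anti-correlation integration.

miRNAs repress their targets, so an mRNA consistently down-regulated in
the tissues where a candidate miRNA is up-regulated is an anti-correlated
putative target.  This module selects genes significantly down in both
tissue DE tables, intersects them with the candidate miRNAs' predicted
target lists, and tallies genes by how many candidates target them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ct_io import MrnaDeTable, TargetMap
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class IntegrationParams:
    """Selection thresholds for the anti-correlation filter."""

    alpha: float = 0.05
    tissues_required: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")


@dataclass
class IntegrationResult:
    """Gene -> targeting candidate miRNAs, with a multiplicity tally."""

    gene_to_mirnas: dict = field(default_factory=dict)  # gene -> sorted list
    tally: dict = field(default_factory=dict)  # k -> number of genes with k miRNAs
    total_genes: int = 0


def select_down_in_both(
    table_a: MrnaDeTable,
    table_b: MrnaDeTable,
    params: IntegrationParams | None = None,
) -> set:
    """Genes down-regulated with p < alpha in BOTH tissue tables.

    Probesets collapse to gene symbols by the any-probeset rule: a gene
    qualifies in a tissue if any of its probesets is down with p < alpha
    there.  The p threshold is strict (< alpha).
    """
    params = params or IntegrationParams()

    def qualifying(table: MrnaDeTable) -> set:
        t = table.table
        hit = (t["direction"] == "down") & (t["p_value"] < params.alpha)
        return set(t.loc[hit, "gene_symbol"])

    genes_a, genes_b = qualifying(table_a), qualifying(table_b)
    if not genes_a or not genes_b:
        logger.warning("a tissue table yields no qualifying down-regulated genes")
    return genes_a & genes_b


def anti_correlate(
    down_genes: set, targets: TargetMap, candidate_mirnas: list
) -> IntegrationResult:
    """Intersect down-regulated genes with candidate miRNAs' target lists.

    A gene enters the result iff it is down in both tissues and predicted
    by at least one candidate; the mapping records exactly which
    candidates target it.
    """
    missing = [m for m in candidate_mirnas if m not in targets]
    if missing:
        raise DataError(f"candidate miRNA(s) absent from target map: {missing}")
    down = {g.upper() for g in down_genes}
    gene_to_mirnas: dict = {}
    for mirna in candidate_mirnas:
        for gene in targets[mirna]:
            if gene.upper() in down:
                gene_to_mirnas.setdefault(gene.upper(), set()).add(mirna)
    gene_to_mirnas = {g: sorted(ms) for g, ms in gene_to_mirnas.items()}
    result = IntegrationResult(
        gene_to_mirnas=gene_to_mirnas,
        total_genes=len(gene_to_mirnas),
    )
    result.tally = tally_by_mirna_count(result)
    return result


def tally_by_mirna_count(result: IntegrationResult) -> dict:
    """Histogram of genes by number of targeting candidate miRNAs."""
    tally: dict = {}
    for mirnas in result.gene_to_mirnas.values():
        k = len(mirnas)
        tally[k] = tally.get(k, 0) + 1
    return tally
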