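"""Database-wide compound screening and coverage-based ranking.

``screen_compounds`` runs the Fisher enrichment test for every testable
compound against every signature, correcting within each signature's family,
and records the significant sets.  Downstream selections — compounds hitting
at least *k* signatures, formulas ranked by how many of a reference compound
set they contain, herbs ranked by how many of their compounds target a gene
set — are thin, deterministic set operations over the screen report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .datamodel import TCMDatabase
from .enrichment import EnrichmentConfig, EnrichmentResult, adjust_family, fisher_enrichment
from .signatures import ContractError, SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Full results of a multi-signature compound screen."""

    config: EnrichmentConfig
    #: signature label -> all per-compound results (testable and not)
    results: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    #: signature label -> set of significant compound ids
    significant: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def signature_labels(self) -> list[str]:
        return list(self.results)

    def significance_counts(self) -> dict[str, int]:
        """compound id -> number of signatures in which it is significant."""
        counts: dict[str, int] = {}
        for sig_compounds in self.significant.values():
            for cid in sig_compounds:
                counts[cid] = counts.get(cid, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, results in self.results.items():
            for r in results:
                rows.append(
                    {
                        "compound_id": r.compound_id,
                        "signature": label,
                        "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                        "odds_ratio": r.odds_ratio,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "significant": r.significant,
                        "untestable": r.untestable,
                    }
                )
        return pd.DataFrame(rows)


def screen_compounds(
    db: TCMDatabase,
    signature_set: SignatureSet | list,
    config: Optional[EnrichmentConfig] = None,
) -> ScreenReport:
    """Test every compound in the database against every signature.

    Adjustment is applied per signature across all testable compounds of
    that signature (each signature is one correction family).  Compounds are
    iterated in sorted-id order so the report is independent of dict
    ordering.
    """
    config = config or EnrichmentConfig()
    report = ScreenReport(config=config)
    sigs = list(signature_set)
    if not sigs:
        return report
    compound_ids = sorted(db.compounds)
    if not any(db.compounds[cid].targets for cid in compound_ids):
        logger.warning("no testable compounds in database")
    for sig in sigs:
        results = [
            fisher_enrichment(
                db.compounds[cid].targets, sig.gene_set, config,
                compound_id=cid, signature_label=sig.label,
            )
            for cid in compound_ids
        ]
        adjust_family(results, config)
        report.results[sig.label] = results
        report.significant[sig.label] = frozenset(
            r.compound_id for r in results if r.significant
        )
    return report


def multi_tissue_compounds(report: ScreenReport, k: int) -> frozenset[str]:
    """Compounds significant in at least ``k`` of the screened signatures."""
    n = len(report.significant)
    if not 1 <= k <= max(n, 1):
        raise ContractError(f"k={k} out of range for {n} screened signatures")
    counts = report.significance_counts()
    return frozenset(cid for cid, c in counts.items() if c >= k)


@dataclass
class CoverageRanking:
    """Entities ranked by how much of a reference set they cover."""

    kind: str  # "formula" | "herb"
    reference: frozenset[str]
    #: (entity_id, covered ids, count) sorted by count desc then id
    rows: list[tuple[str, frozenset[str], int]] = field(default_factory=list)

    def top(self, n: int = 1) -> list[tuple[str, frozenset[str], int]]:
        return self.rows[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"entity_id": eid, "coverage": cnt, "covered": ";".join(sorted(cov))}
                for eid, cov, cnt in self.rows
            ]
        )


def _ranked(kind: str, reference: frozenset[str], cover: dict[str, frozenset[str]]) -> CoverageRanking:
    rows = [(eid, cov, len(cov)) for eid, cov in cover.items()]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return CoverageRanking(kind=kind, reference=reference, rows=rows)


def rank_formulas_by_coverage(db: TCMDatabase, compound_set: Iterable[str]) -> CoverageRanking:
    """Rank formulas by the number of reference compounds they contain.

    A formula covers a compound iff some herb in the formula contains it.
    Coverage is unweighted presence/absence; ties break lexicographically by
    formula id.
    """
    ref = frozenset(compound_set)
    cover = {fid: db.formula_compounds(fid) & ref for fid in db.formulas}
    return _ranked("formula", ref, cover)


def rank_herbs_by_coverage(db: TCMDatabase, compound_set: Iterable[str]) -> CoverageRanking:
    """Rank herbs by the number of reference compounds they contain."""
    ref = frozenset(compound_set)
    cover = {hid: db.herbs[hid].compounds & ref for hid in db.herbs}
    return _ranked("herb", ref, cover)


def rank_herbs_by_gene_targeting(
    db: TCMDatabase,
    gene_set: Iterable[str],
    metric: str = "compound-count",
) -> CoverageRanking:
    """Rank herbs by how many of their compounds target genes in ``gene_set``.

    Default metric counts *compounds* with at least one target in the set
    (``covered`` records those compound ids).  The alternative
    ``distinct-gene-count`` metric ranks by the number of distinct set genes
    the herb's compounds collectively hit; ``covered`` then records genes.
    """
    genes = frozenset(gene_set)
    if not genes:
        raise ContractError("gene_set is empty")
    cover: dict[str, frozenset[str]] = {}
    for hid, herb in db.herbs.items():
        if metric == "compound-count":
            cover[hid] = frozenset(
                cid for cid in herb.compounds if db.compounds[cid].targets & genes
            )
        elif metric == "distinct-gene-count":
            hit: set[str] = set()
            for cid in herb.compounds:
                hit |= db.compounds[cid].targets & genes
            cover[hid] = frozenset(hit)
        else:
            raise ContractError(f"unknown metric {metric!r}")
    return _ranked("herb", genes, cover)
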