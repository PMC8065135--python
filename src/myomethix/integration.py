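"""Methylation-expression correlation screen and candidate prioritisation.

Maps CpG probes to differentially expressed genes via the manifest,
correlates probe methylation with gene expression across subjects of one
state (both groups pooled by default), summarises the genomic context of
negatively correlated sites against all screened sites with a
goodness-of-fit chi-square, and applies the candidate filter: reduced
expression in both states plus at least one inversely correlated CpG.

The correlation screen is deliberately left at nominal p < 0.05 (no
multiple-testing correction); the column is labeled ``p_nominal`` in
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .diffexpr import DEResult
from .errors import DegenerateInputError, ValidationError
from .formats_io import BetaMatrix, ExpressionMatrix, ProbeManifest, SampleSheet

log = logging.getLogger(__name__)

__all__ = [
    "ProbeGenePair",
    "CorrelationRecord",
    "CandidateGene",
    "map_probes_to_de_genes",
    "correlation_screen",
    "context_enrichment",
    "ContextEnrichment",
    "prioritize_candidates",
]


@dataclass(frozen=True)
class ProbeGenePair:
    probe_id: str
    gene: str
    gene_region: str
    island_region: str


@dataclass(frozen=True)
class CorrelationRecord:
    """One probe-gene correlation; ``sign_class`` follows sign(r)."""

    probe_id: str
    gene: str
    r: float
    p: float
    n: int
    method: str
    sign_class: str
    gene_region: str
    island_region: str

    def __post_init__(self):
        expected = "negative" if self.r < 0 else "positive"
        if self.sign_class != expected:
            raise ValidationError("sign_class inconsistent with r")


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    de_q_myoblast: float
    de_q_myotube: float
    direction: str
    n_negative_cpgs: int
    flags: frozenset[str]


def map_probes_to_de_genes(manifest: ProbeManifest, de_genes) -> list[ProbeGenePair]:
    """All manifest rows whose nearest gene is differentially expressed.

    Multi-gene probes contribute one pair per matching gene.
    """
    rows = manifest.rows_for_genes(de_genes)
    return [ProbeGenePair(str(r.probe_id), str(r.nearest_gene),
                          str(r.gene_region), str(r.island_region))
            for r in rows.itertuples(index=False)]


def correlation_screen(beta: BetaMatrix, expr: ExpressionMatrix,
                       pairs: list[ProbeGenePair], samples: SampleSheet,
                       state: str, method: str = "spearman",
                       group: str | None = None) -> list[CorrelationRecord]:
    """Correlate probe methylation with gene expression per pair.

    Subjects of the requested state present in BOTH matrices are used
    (both groups pooled unless ``group`` is given).  Pairs whose probe or
    gene row is missing, or with zero variance, are skipped with a
    tallied warning.
    """
    sheet = samples.subset(state=state, group=group)
    ids = [s for s in sheet["sample_id"]
           if s in set(beta.sample_ids) and s in set(expr.sample_ids)]
    dropped = len(sheet) - len(ids)
    if dropped:
        log.warning("dropping %d sample(s) missing from one matrix", dropped)
    if len(ids) < 3:
        raise ValidationError("correlation screen needs >= 3 overlapping samples")
    beta_sub = beta.subset_samples(ids)
    expr_sub = expr.subset_samples(ids)
    bindex = beta_sub.feature_index
    eindex = expr_sub.feature_index
    records = []
    skipped_missing = skipped_degenerate = 0
    for pair in pairs:
        bi = bindex.get(pair.probe_id)
        ei = eindex.get(pair.gene)
        if bi is None or ei is None:
            skipped_missing += 1
            continue
        try:
            res = stats_core.correlation(beta_sub.values[bi], expr_sub.values[ei],
                                         method=method)
        except DegenerateInputError:
            skipped_degenerate += 1
            continue
        records.append(CorrelationRecord(
            probe_id=pair.probe_id, gene=pair.gene, r=res.estimate, p=res.p,
            n=len(ids), method=method,
            sign_class="negative" if res.estimate < 0 else "positive",
            gene_region=pair.gene_region, island_region=pair.island_region))
    if skipped_missing or skipped_degenerate:
        log.warning("correlation screen skipped %d pair(s) with missing rows "
                    "and %d degenerate pair(s)", skipped_missing, skipped_degenerate)
    return records


def nominal_negative(records, p_threshold: float = 0.05) -> list[CorrelationRecord]:
    """Records with a negative correlation at nominal significance."""
    return [r for r in records if r.sign_class == "negative" and r.p < p_threshold]


@dataclass
class ContextEnrichment:
    """Frequency tables and goodness-of-fit tests per classification scheme."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    tests: dict[str, stats_core.TestResult] = field(default_factory=dict)


def context_enrichment(foreground: list[CorrelationRecord],
                       background: list[CorrelationRecord]) -> ContextEnrichment:
    """Genomic-context distribution of foreground vs all screened records.

    Record-level tallies (a probe mapped to two genes counts twice, as it
    was screened twice); expected proportions come from the background.
    """
    if not foreground or not background:
        raise ValidationError("foreground and background must be non-empty")
    result = ContextEnrichment()
    for scheme in ("gene_region", "island_region"):
        fg = pd.Series([getattr(r, scheme) for r in foreground]).value_counts()
        bg = pd.Series([getattr(r, scheme) for r in background]).value_counts()
        extra = set(fg.index) - set(bg.index)
        if extra:
            raise ValidationError(
                f"foreground categories absent from background: {sorted(extra)}")
        categories = sorted(bg.index)
        fg_counts = np.array([fg.get(c, 0) for c in categories], dtype=float)
        bg_counts = np.array([bg[c] for c in categories], dtype=float)
        expected = bg_counts / bg_counts.sum() * fg_counts.sum()
        result.tables[scheme] = pd.DataFrame({
            "category": categories,
            "foreground_count": fg_counts.astype(int),
            "foreground_pct": fg_counts / fg_counts.sum() * 100.0,
            "background_count": bg_counts.astype(int),
            "background_pct": bg_counts / bg_counts.sum() * 100.0,
        })
        result.tests[scheme] = stats_core.chi2_test(fg_counts, expected)
    return result


def prioritize_candidates(de_myoblast: list[DEResult], de_myotube: list[DEResult],
                          records: list[CorrelationRecord],
                          q_threshold: float = 0.05,
                          corr_p_threshold: float = 0.05) -> list[CandidateGene]:
    """Genes down-regulated in BOTH states with >= 1 inverse correlation.

    Literature-based novelty triage is human judgment and deliberately
    not automated.  Sorted by myoblast q.
    """
    down_b = {r.gene: r.q for r in de_myoblast
              if r.q < q_threshold and r.direction == "down"}
    down_t = {r.gene: r.q for r in de_myotube
              if r.q < q_threshold and r.direction == "down"}
    negative_counts: dict[str, int] = {}
    for r in nominal_negative(records, corr_p_threshold):
        negative_counts[r.gene] = negative_counts.get(r.gene, 0) + 1
    candidates = []
    for gene in sorted(set(down_b) & set(down_t)):
        n_neg = negative_counts.get(gene, 0)
        if n_neg < 1:
            continue
        candidates.append(CandidateGene(
            gene=gene, de_q_myoblast=down_b[gene], de_q_myotube=down_t[gene],
            direction="down", n_negative_cpgs=n_neg,
            flags=frozenset({"down_in_both", "inverse_correlated"})))
    return sorted(candidates, key=lambda c: (c.de_q_myoblast, c.gene))
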