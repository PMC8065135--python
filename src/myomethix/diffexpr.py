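"""Case-vs-control differential expression and gene ranking.

Per-gene OLS of log2 expression on group (T2D vs NGT) adjusted for age,
BMI and sex (female = 0), BH FDR across tested genes, fold change as
2**coefficient, t-statistic ranking for preranked enrichment, and the
cross-state overlap partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import stats_core
from .errors import ValidationError
from .formats_io import ExpressionMatrix, SampleSheet

log = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "collapse_probes_to_genes",
    "differential_expression",
    "rank_genes",
    "cross_state_overlap",
    "CrossStateOverlap",
]

COLLAPSE_RULES = ("highest_mean", "most_detected")


@dataclass(frozen=True)
class DEResult:
    """Per-gene group effect: log2 coefficient (T2D - NGT), fold change,
    t, p, BH q and up/down direction."""

    gene: str
    coefficient: float
    fold_change: float
    t: float
    p: float
    q: float
    direction: str

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValidationError(f"invalid direction {self.direction!r}")


def collapse_probes_to_genes(expr: ExpressionMatrix, probe_to_gene: dict,
                             rule: str = "highest_mean",
                             detection_threshold: float | None = None) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one representative row per gene.

    ``highest_mean`` keeps the probe with the highest mean intensity
    across samples (an interpretation of picking the dominant probe);
    ``most_detected`` keeps the probe exceeding ``detection_threshold``
    (default: matrix-wide median) in the most samples, ties broken by
    mean.  Both rules break remaining ties by probe id for determinism.
    """
    if rule not in COLLAPSE_RULES:
        raise ValidationError(f"unknown collapse rule {rule!r}")
    if not probe_to_gene:
        raise ValidationError("empty probe-to-gene mapping")
    if detection_threshold is None:
        detection_threshold = float(np.median(expr.values))
    index = expr.feature_index
    per_gene: dict[str, list[str]] = {}
    for probe, gene in probe_to_gene.items():
        if probe in index and gene:
            per_gene.setdefault(gene, []).append(probe)

    def score(probe: str):
        row = expr.values[index[probe]]
        mean = float(row.mean())
        if rule == "highest_mean":
            return (mean, probe)
        return (int((row > detection_threshold).sum()), mean, probe)

    genes = sorted(per_gene)
    chosen = [max(per_gene[g], key=score) for g in genes]
    values = expr.values[[index[p] for p in chosen]]
    return ExpressionMatrix(tuple(genes), expr.sample_ids, values)


def differential_expression(expr: ExpressionMatrix, samples: SampleSheet,
                            state: str) -> list[DEResult]:
    """Covariate-adjusted group screen on one state's samples.

    Genes constant across samples are skipped with a warning rather than
    reported as NaN; q-values cover all tested genes.
    """
    if state not in ("myoblast", "myotube"):
        raise ValidationError(f"unknown state {state!r}")
    sheet = samples.subset(state=state)
    ids = [s for s in sheet["sample_id"] if s in set(expr.sample_ids)]
    groups = set(sheet.set_index("sample_id").loc[ids, "group"])
    if groups != {"NGT", "T2D"}:
        raise ValidationError(
            f"both groups must be represented in state {state!r}; found {sorted(groups)}")
    sub = expr.subset_samples(ids)
    g = samples.group_indicator(ids)
    cov = samples.covariates(ids)
    coef, t, p, _, degenerate = stats_core.linear_model_group_tests(sub.values, g, cov)
    if degenerate.any():
        skipped = [sub.feature_ids[i] for i in np.flatnonzero(degenerate)]
        log.warning("skipping %d constant gene(s): %s%s", len(skipped),
                    ", ".join(skipped[:5]), "..." if len(skipped) > 5 else "")
    keep = np.flatnonzero(~degenerate)
    q = stats_core.bh_fdr(p[keep]).q
    results = []
    for qi, i in zip(q, keep):
        c = float(coef[i])
        results.append(DEResult(
            gene=sub.feature_ids[i], coefficient=c, fold_change=float(2.0 ** c),
            t=float(t[i]), p=float(p[i]), q=float(qi),
            direction="down" if c < 0 else "up"))
    return results


def rank_genes(de: list[DEResult]) -> list[tuple[str, float]]:
    """Rank by descending t; ties broken alphabetically by gene symbol."""
    if not de:
        raise ValidationError("cannot rank an empty result list")
    return [(r.gene, r.t) for r in sorted(de, key=lambda r: (-r.t, r.gene))]


@dataclass(frozen=True)
class CrossStateOverlap:
    """Partition of genes significant in either state."""

    shared_concordant: frozenset[str]
    shared_discordant: frozenset[str]
    myoblast_only: frozenset[str]
    myotube_only: frozenset[str]


def cross_state_overlap(de_myoblast: list[DEResult], de_myotube: list[DEResult],
                        q_threshold: float = 0.05) -> CrossStateOverlap:
    """Split significant genes into shared (con/discordant) and state-only."""
    sig_b = {r.gene: r.direction for r in de_myoblast if r.q < q_threshold}
    sig_t = {r.gene: r.direction for r in de_myotube if r.q < q_threshold}
    shared = set(sig_b) & set(sig_t)
    concordant = frozenset(g for g in shared if sig_b[g] == sig_t[g])
    return CrossStateOverlap(
        shared_concordant=concordant,
        shared_discordant=frozenset(shared) - concordant,
        myoblast_only=frozenset(set(sig_b) - shared),
        myotube_only=frozenset(set(sig_t) - shared))
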