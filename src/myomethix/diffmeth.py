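"""Paired myoblast-vs-myotube methylation dynamics.

Per-group subject-paired Wilcoxon signed-rank tests on beta fractions
(rank tests are scale invariant, percent appears only in reports),
within-group BH FDR, cross-group overlap of significant sites, detection
of sites moving in strictly opposite directions in the two groups,
region-class average methylation contrasts and PCA-group association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .errors import ValidationError
from .formats_io import (
    DYNAMICS_REPORT_COLUMNS,
    BetaMatrix,
    GENE_REGIONS,
    ISLAND_REGIONS,
    ProbeManifest,
    SampleSheet,
    _header_lines,
)

log = logging.getLogger(__name__)

__all__ = [
    "DynamicsRecord",
    "PairedDynamics",
    "OppositeSiteRecord",
    "paired_dynamics",
    "dynamics_overlap",
    "opposite_direction_sites",
    "write_dynamics_report",
    "region_average_methylation",
    "pc_group_association",
]


@dataclass(frozen=True)
class DynamicsRecord:
    """Per-probe paired differentiation contrast for one group.

    Means/SDs are on the percent scale; ``difference`` is the signed
    myotube - myoblast change in percentage points at full precision
    (reports round to 1 decimal).
    """

    probe_id: str
    group: str
    mean_myoblast: float
    sd_myoblast: float
    mean_myotube: float
    sd_myotube: float
    difference: float
    w: float
    p: float
    q: float
    n: int
    chromosome: str = ""
    gene: str = ""
    gene_region: str = ""
    island_region: str = ""


@dataclass(frozen=True)
class PairedDynamics:
    """Both groups' dynamics records for one probe (report row shape)."""

    probe_id: str
    ngt: DynamicsRecord
    t2d: DynamicsRecord
    chromosome: str = ""
    gene: str = ""
    gene_region: str = ""
    island_region: str = ""


def split_paired(pairs) -> tuple[list[DynamicsRecord], list[DynamicsRecord]]:
    """Split parsed report rows into (NGT records, T2D records)."""
    return [p.ngt for p in pairs], [p.t2d for p in pairs]


@dataclass(frozen=True)
class OppositeSiteRecord:
    """A probe significant in both groups with oppositely signed changes."""

    probe_id: str
    ngt: DynamicsRecord
    t2d: DynamicsRecord
    chromosome: str = ""
    gene: str = ""
    gene_region: str = ""
    island_region: str = ""


def paired_dynamics(beta: BetaMatrix, samples: SampleSheet, group: str,
                    manifest: ProbeManifest | None = None,
                    mode: str = "auto") -> list[DynamicsRecord]:
    """Subject-paired signed-rank dynamics for every probe in one group.

    q-values come from BH FDR across all probes within the group.
    Subjects lacking one of the two states are excluded with a warning.
    """
    if group not in ("NGT", "T2D"):
        raise ValidationError(f"unknown group {group!r}")
    subjects = samples.paired_subjects(group)
    all_subjects = sorted(set(samples.subset(group=group)["subject_id"]))
    unpaired = sorted(set(all_subjects) - set(subjects))
    if unpaired:
        log.warning("excluding unpaired subjects from %s dynamics: %s",
                    group, unpaired)
    if len(subjects) < 3:
        raise ValidationError(
            f"paired dynamics needs >= 3 paired subjects in {group}, "
            f"found {len(subjects)}")
    blast_ids = [samples.sample_for(s, "myoblast") for s in subjects]
    tube_ids = [samples.sample_for(s, "myotube") for s in subjects]
    available = set(beta.sample_ids)
    keep = [i for i, (b, t) in enumerate(zip(blast_ids, tube_ids))
            if b in available and t in available]
    if len(keep) < len(subjects):
        log.warning("excluding %d subject(s) without beta columns",
                    len(subjects) - len(keep))
    if len(keep) < 3:
        raise ValidationError("fewer than 3 paired subjects with beta data")
    blast = beta.subset_samples([blast_ids[i] for i in keep]).values
    tube = beta.subset_samples([tube_ids[i] for i in keep]).values
    n = len(keep)

    W, P = stats_core.paired_signed_rank_tests(tube, blast, mode=mode)
    q = stats_core.bh_fdr(P).q

    mean_b = blast.mean(axis=1) * 100.0
    sd_b = blast.std(axis=1, ddof=1) * 100.0
    mean_t = tube.mean(axis=1) * 100.0
    sd_t = tube.std(axis=1, ddof=1) * 100.0
    diff = mean_t - mean_b

    records = []
    for i, probe in enumerate(beta.feature_ids):
        annotation = (manifest.annotation_for(probe) if manifest is not None
                      else {"chromosome": "", "nearest_gene": "",
                            "gene_region": "", "island_region": ""})
        records.append(DynamicsRecord(
            probe_id=probe, group=group,
            mean_myoblast=float(mean_b[i]), sd_myoblast=float(sd_b[i]),
            mean_myotube=float(mean_t[i]), sd_myotube=float(sd_t[i]),
            difference=float(diff[i]), w=float(W[i]), p=float(P[i]),
            q=float(q[i]), n=n,
            chromosome=annotation["chromosome"],
            gene=annotation["nearest_gene"],
            gene_region=annotation["gene_region"],
            island_region=annotation["island_region"]))
    return records


@dataclass(frozen=True)
class DynamicsOverlap:
    """Up/down significant probe sets per group and their intersections."""

    increased_ngt: frozenset[str]
    increased_t2d: frozenset[str]
    decreased_ngt: frozenset[str]
    decreased_t2d: frozenset[str]

    @property
    def increased_shared(self) -> frozenset[str]:
        return self.increased_ngt & self.increased_t2d

    @property
    def decreased_shared(self) -> frozenset[str]:
        return self.decreased_ngt & self.decreased_t2d

    def counts(self) -> dict[str, int]:
        return {
            "increased_ngt": len(self.increased_ngt),
            "increased_t2d": len(self.increased_t2d),
            "increased_shared": len(self.increased_shared),
            "decreased_ngt": len(self.decreased_ngt),
            "decreased_t2d": len(self.decreased_t2d),
            "decreased_shared": len(self.decreased_shared),
        }


def dynamics_overlap(ngt, t2d, q_threshold: float = 0.05) -> DynamicsOverlap:
    """Significant increased/decreased sets per group plus intersections."""
    def sig(records, sign):
        return frozenset(r.probe_id for r in records
                         if r.q < q_threshold and sign * r.difference > 0)

    return DynamicsOverlap(
        increased_ngt=sig(ngt, +1), increased_t2d=sig(t2d, +1),
        decreased_ngt=sig(ngt, -1), decreased_t2d=sig(t2d, -1))


def opposite_direction_sites(ngt, t2d, q_threshold: float = 0.05) -> list[OppositeSiteRecord]:
    """Probes with q < threshold in BOTH groups and strictly opposite signs."""
    t2d_by_probe = {r.probe_id: r for r in t2d}
    out = []
    for r_ngt in ngt:
        r_t2d = t2d_by_probe.get(r_ngt.probe_id)
        if r_t2d is None:
            continue
        if r_ngt.q >= q_threshold or r_t2d.q >= q_threshold:
            continue
        if r_ngt.difference * r_t2d.difference >= 0:
            continue
        out.append(OppositeSiteRecord(
            probe_id=r_ngt.probe_id, ngt=r_ngt, t2d=r_t2d,
            chromosome=r_ngt.chromosome or r_t2d.chromosome,
            gene=r_ngt.gene or r_t2d.gene,
            gene_region=r_ngt.gene_region or r_t2d.gene_region,
            island_region=r_ngt.island_region or r_t2d.island_region))
    return out


def write_dynamics_report(ngt, t2d, path, header: dict | None = None,
                          decimals: int = 1) -> None:
    """Write a per-probe report joining both groups (the dialect that
    :func:`myomethix.formats_io.parse_dynamics_report` reads).

    Percent fields are rounded to ``decimals``; p and q keep 4 decimals.
    """
    t2d_by_probe = {r.probe_id: r for r in t2d}
    rows = []
    for r in ngt:
        other = t2d_by_probe.get(r.probe_id)
        if other is None:
            continue
        row = {"probe_id": r.probe_id, "chromosome": r.chromosome,
               "gene": r.gene, "gene_region": r.gene_region,
               "island_region": r.island_region}
        for prefix, rec in (("ngt", r), ("t2d", other)):
            row[f"{prefix}_myoblast_mean"] = round(rec.mean_myoblast, decimals)
            row[f"{prefix}_myoblast_sd"] = round(rec.sd_myoblast, decimals)
            row[f"{prefix}_myotube_mean"] = round(rec.mean_myotube, decimals)
            row[f"{prefix}_myotube_sd"] = round(rec.sd_myotube, decimals)
            row[f"{prefix}_difference"] = round(rec.difference, decimals)
            row[f"{prefix}_p"] = round(rec.p, 4)
            row[f"{prefix}_q"] = round(rec.q, 4)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=DYNAMICS_REPORT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region-class averages and PCA association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionContrast:
    scheme: str
    category: str
    kind: str            # "group" (T2D vs NGT) or "state" (myotube vs myoblast)
    stratum: str         # state for group contrasts, group for state contrasts
    estimate: float
    statistic: float
    p: float
    q: float = float("nan")


@dataclass
class RegionAverages:
    """Per-sample class-average methylation plus contrasts.

    ``means`` maps scheme name ("gene_region" / "island_region") to a
    sample x class DataFrame of mean beta fractions.
    """

    means: dict[str, pd.DataFrame]
    contrasts: list[RegionContrast] = field(default_factory=list)


def region_average_methylation(beta: BetaMatrix, manifest: ProbeManifest,
                               samples: SampleSheet) -> RegionAverages:
    """Average beta per sample within each gene-region / island class.

    Group contrasts use the covariate-adjusted linear model per state;
    state contrasts use paired signed-rank tests within each group.
    Classes with no probes are omitted with a warning.
    """
    frame = manifest.frame
    index = beta.feature_index
    means: dict[str, pd.DataFrame] = {}
    for scheme, categories in (("gene_region", GENE_REGIONS),
                               ("island_region", ISLAND_REGIONS)):
        columns = {}
        seen = frame.drop_duplicates(subset=["probe_id", scheme])
        for cat in categories:
            probes = [p for p in seen.loc[seen[scheme] == cat, "probe_id"]
                      if p in index]
            if not probes:
                log.warning("no probes in class %s/%s; omitted", scheme, cat)
                continue
            rows = [index[p] for p in probes]
            columns[cat] = beta.values[rows].mean(axis=0)
        means[scheme] = pd.DataFrame(columns, index=list(beta.sample_ids))

    contrasts: list[RegionContrast] = []
    for scheme, table in means.items():
        batch: list[RegionContrast] = []
        for state in ("myoblast", "myotube"):
            sheet = samples.subset(state=state)
            ids = [s for s in sheet["sample_id"] if s in table.index]
            if len(set(sheet.set_index("sample_id").loc[ids, "group"])) < 2:
                continue
            y_all = table.loc[ids]
            g = samples.group_indicator(ids)
            cov = samples.covariates(ids)
            for cat in table.columns:
                res = stats_core.linear_model_group_test(y_all[cat].to_numpy(), g, cov)
                batch.append(RegionContrast(scheme, cat, "group", state,
                                            res.estimate, res.statistic, res.p))
        for group in ("NGT", "T2D"):
            subjects = samples.paired_subjects(group)
            pairs = [(samples.sample_for(s, "myoblast"),
                      samples.sample_for(s, "myotube")) for s in subjects]
            pairs = [(b, t) for b, t in pairs if b in table.index and t in table.index]
            if len(pairs) < 3:
                continue
            for cat in table.columns:
                blast = table.loc[[b for b, _ in pairs], cat].to_numpy()
                tube = table.loc[[t for _, t in pairs], cat].to_numpy()
                res = stats_core.wilcoxon_signed_rank(tube, blast)
                batch.append(RegionContrast(scheme, cat, "state", group,
                                            float((tube - blast).mean()),
                                            res.statistic, res.p))
        if batch:
            q = stats_core.bh_fdr([c.p for c in batch]).q
            contrasts.extend(
                RegionContrast(c.scheme, c.category, c.kind, c.stratum,
                               c.estimate, c.statistic, c.p, float(qi))
                for c, qi in zip(batch, q))
    return RegionAverages(means=means, contrasts=contrasts)


def pc_group_association(beta: BetaMatrix, samples: SampleSheet, state: str,
                         k: int = 10) -> list[stats_core.TestResult]:
    """Point-biserial correlation of top PCA scores with the group label.

    One state at a time; returns one Pearson :class:`TestResult` per
    component, in component order.
    """
    if state not in ("myoblast", "myotube"):
        raise ValidationError(f"unknown state {state!r}")
    sheet = samples.subset(state=state)
    ids = [s for s in sheet["sample_id"] if s in set(beta.sample_ids)]
    if len(ids) < 3:
        raise ValidationError("need >= 3 samples for PCA association")
    k = min(k, len(ids) - 1)
    sub = beta.subset_samples(ids)
    scores, _ = stats_core.pca_top_components(sub.values, k)
    g = samples.group_indicator(ids)
    results = []
    for i in range(k):
        results.append(stats_core.correlation(scores[:, i], g, method="pearson"))
    return results
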