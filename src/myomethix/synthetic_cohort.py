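"""Synthetic paired two-state cohorts with planted signal and ground truth.

Generates a matched expression matrix, methylation beta matrix, probe
manifest, sample sheet, promoter sequences, a motif model, gene sets and
a term-annotation table with the statistical structure the analyses
assume: planted case-vs-control expression effects, TSS-concentrated
negative methylation-expression couplings, asymmetric differentiation
dynamics between groups, opposite-direction sites and motif-bearing
promoters — all keyed to a single integer seed, with a ground-truth
table for sensitivity/FDR evaluation.

Beta values are drawn on the logit scale (two baseline modes, hypo ~0.1
and hyper ~0.9) and inverse-logit transformed, so [0, 1] holds by
construction and couplings can be injected additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ValidationError
from .formats_io import (
    BetaMatrix,
    CohortBundle,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MotifModel,
    ProbeManifest,
    SampleSheet,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "evaluate_calls",
           "consensus_motif"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    n_per_group: int = 14
    n_genes: int = 2000
    n_probes: int = 10000
    frac_de_genes: float = 0.05
    de_effect_log2: float = 1.0
    expr_sd: float = 0.5
    both_state_frac: float = 0.5          # DE genes carrying the effect in both states
    n_candidate_genes: int = 10           # forced down-in-both + coupled genes
    coupling_frac: float = 0.6
    coupling_strength: float = 0.8
    coupling_tss_frac: float = 0.8        # coupled probes placed at TSS200/TSS1500
    dynamics_frac_ngt: float = 0.05
    dynamics_ratio_t2d: float = 2.0
    dynamics_shared_frac: float = 0.5     # fraction of NGT dynamic probes shared
    n_opposite_sites: int = 39
    dynamics_shift_lo_pp: float = 5.0
    dynamics_shift_hi_pp: float = 15.0
    beta_noise_logit: float = 0.05
    annotated_frac: float = 0.7
    opensea_offset_t2d_pp: float = 0.0    # planted case offset in open-sea probes
    motif_frac_fg: float = 0.9
    motif_frac_bg: float = 0.05
    motif_consensus: str = "GACAGCTGTC"
    promoter_length: int = 1000
    n_random_sets: int = 20
    age_mean: float = 56.0
    age_sd: float = 7.0
    bmi_mean: float = 25.7
    bmi_sd: float = 3.1

    def validate(self) -> None:
        for name in ("frac_de_genes", "both_state_frac", "coupling_frac",
                     "coupling_tss_frac", "dynamics_frac_ngt",
                     "dynamics_shared_frac", "motif_frac_fg", "motif_frac_bg",
                     "annotated_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.coupling_strength <= 1.0:
            raise ValidationError("coupling_strength must be in (0, 1]")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        n_de = round(self.frac_de_genes * self.n_genes)
        if n_de < 1:
            raise ValidationError("frac_de_genes * n_genes < 1: no DE genes to plant")
        if self.n_candidate_genes > n_de:
            raise ValidationError("n_candidate_genes exceeds the planted DE genes")
        if round(self.both_state_frac * n_de) < self.n_candidate_genes:
            raise ValidationError("both_state_frac too small for n_candidate_genes")
        if round(self.coupling_frac * n_de) < self.n_candidate_genes:
            raise ValidationError("coupling_frac too small for n_candidate_genes")
        if self.n_opposite_sites > self.n_probes:
            raise ValidationError("n_opposite_sites exceeds n_probes")
        n_dyn = self._dynamics_layout()
        if sum(n_dyn.values()) + round(self.coupling_frac * n_de) > self.n_probes:
            raise ValidationError("planted probe sets exceed n_probes")
        if len(self.motif_consensus) < 1 or set(self.motif_consensus) - set("ACGT"):
            raise ValidationError("motif_consensus must be a non-empty ACGT string")
        if self.promoter_length < len(self.motif_consensus):
            raise ValidationError("promoter shorter than the motif")

    def _dynamics_layout(self) -> dict[str, int]:
        """Sizes of the planted dynamic probe blocks.

        NGT total = opposite + shared + ngt_only; the T2D total is
        exactly ``dynamics_ratio_t2d`` times the NGT total.
        """
        m_ngt = round(self.dynamics_frac_ngt * self.n_probes)
        m_t2d = round(m_ngt * self.dynamics_ratio_t2d)
        if m_ngt < self.n_opposite_sites:
            raise ValidationError("dynamics_frac_ngt too small for n_opposite_sites")
        if m_t2d < self.n_opposite_sites:
            raise ValidationError("dynamics ratio too small for n_opposite_sites")
        shared = min(round(self.dynamics_shared_frac * m_ngt),
                     m_ngt - self.n_opposite_sites,
                     m_t2d - self.n_opposite_sites)
        return {
            "opposite": self.n_opposite_sites,
            "shared": shared,
            "ngt_only": m_ngt - self.n_opposite_sites - shared,
            "t2d_only": m_t2d - self.n_opposite_sites - shared,
        }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted signal, keyed by ids that exist in the generated bundle."""

    de_genes: dict[str, dict] = field(default_factory=dict)   # gene -> effect, both_states
    coupled_pairs: list[tuple[str, str]] = field(default_factory=list)
    dynamic_probes: dict[str, dict[str, float]] = field(default_factory=dict)
    opposite_probes: list[str] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    motif_genes: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)

    def de_gene_ids(self) -> set[str]:
        return set(self.de_genes)

    def down_gene_ids(self) -> set[str]:
        return {g for g, info in self.de_genes.items() if info["effect"] < 0}


@dataclass
class SimulatedCohort:
    bundle: CohortBundle
    truth: GroundTruth
    gene_sets: GeneSetCollection
    promoters: dict[str, str]
    motif: MotifModel
    term_annotation: pd.DataFrame


def consensus_motif(name: str, consensus: str, strength: float = 0.97) -> MotifModel:
    """Near-deterministic PFM whose consensus equals the given string."""
    L = len(consensus)
    counts = np.full((4, L), (1.0 - strength) / 3.0 * 100.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = strength * 100.0
    return MotifModel(name=name, counts=counts)


def _simulate_samples(cfg: SimulationConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    for group, prefix in (("NGT", "N"), ("T2D", "D")):
        ages = rng.normal(cfg.age_mean, cfg.age_sd, cfg.n_per_group)
        bmis = rng.normal(cfg.bmi_mean, cfg.bmi_sd, cfg.n_per_group)
        for i in range(cfg.n_per_group):
            subject = f"{prefix}{i + 1:03d}"
            sex = "male" if i % 2 == 0 else "female"   # balanced by construction
            for state in ("myoblast", "myotube"):
                rows.append({
                    "sample_id": f"{subject}_{state}",
                    "subject_id": subject, "group": group, "state": state,
                    "age": round(float(ages[i]), 1),
                    "bmi": round(float(bmis[i]), 1), "sex": sex,
                })
    return SampleSheet(pd.DataFrame(rows))


def _plan_de_genes(cfg: SimulationConfig, genes: list[str],
                   rng: np.random.Generator) -> tuple[dict, list[str], list[str]]:
    """Choose DE genes with signs, both-state flags and coupling slots.

    The first ``n_candidate_genes`` are forced down-in-both-states and
    coupled; extra coupled genes are drawn so that no other gene is
    simultaneously (down, both states, coupled) — making the candidate
    truth set exact.
    """
    n_de = round(cfg.frac_de_genes * cfg.n_genes)
    de_genes = list(rng.choice(genes, size=n_de, replace=False))
    candidates = de_genes[: cfg.n_candidate_genes]
    others = de_genes[cfg.n_candidate_genes:]
    n_both = round(cfg.both_state_frac * n_de)
    extra_both = list(rng.choice(others, size=n_both - len(candidates),
                                 replace=False)) if n_both > len(candidates) else []
    both_set = set(candidates) | set(extra_both)

    # only the forced candidates are down in both states, keeping the
    # candidate ground truth exact; other both-state genes go up, genes
    # with a single-state effect get a random sign
    signs = {g: -1.0 for g in candidates}
    for g in extra_both:
        signs[g] = 1.0
    for g in others:
        if g not in signs:
            signs[g] = float(rng.choice([-1.0, 1.0]))

    n_coupled = round(cfg.coupling_frac * n_de)
    need = n_coupled - len(candidates)
    if need > len(others):
        raise ValidationError("coupling_frac too large for the DE gene pool")
    coupled_genes = candidates + list(rng.choice(others, size=need, replace=False))

    info = {g: {"effect": signs[g] * cfg.de_effect_log2, "both_states": g in both_set}
            for g in de_genes}
    return info, coupled_genes, candidates


def _simulate_expression(cfg, genes, samples: SampleSheet, de_info,
                         rng) -> ExpressionMatrix:
    frame = samples.frame
    n_samples = len(frame)
    is_t2d = (frame["group"] == "T2D").to_numpy()
    is_tube = (frame["state"] == "myotube").to_numpy()
    age = frame["age"].to_numpy(float)
    sex = (frame["sex"] == "male").to_numpy(float)
    age_z = (age - age.mean()) / (age.std() or 1.0)

    baseline = rng.normal(8.0, 2.0, len(genes))
    age_coef = rng.normal(0.0, 0.05, len(genes))
    sex_coef = rng.normal(0.0, 0.05, len(genes))
    values = (baseline[:, None]
              + age_coef[:, None] * age_z[None, :]
              + sex_coef[:, None] * sex[None, :]
              + rng.normal(0.0, cfg.expr_sd, (len(genes), n_samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, info in de_info.items():
        mask = is_t2d if info["both_states"] else (is_t2d & ~is_tube)
        values[gene_index[gene], mask] += info["effect"]
    return ExpressionMatrix(tuple(genes), tuple(frame["sample_id"]), values)


def _assign_manifest(cfg, probes, genes, coupled_probes, coupled_genes,
                     rng) -> ProbeManifest:
    n = len(probes)
    region_choices = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"]
    region_probs = [0.10, 0.15, 0.10, 0.08, 0.45, 0.12]
    annotated = rng.random(n) < cfg.annotated_frac
    nearest = np.where(annotated, rng.choice(genes, size=n), "")
    regions = np.where(annotated,
                       rng.choice(region_choices, size=n, p=region_probs),
                       "intergenic")
    # coupled probes are pinned to their gene, mostly at the proximal promoter
    for probe, gene in zip(coupled_probes, coupled_genes):
        i = probes.index(probe)
        nearest[i] = gene
        if rng.random() < cfg.coupling_tss_frac:
            regions[i] = rng.choice(["TSS200", "TSS1500"])
        else:
            regions[i] = rng.choice(region_choices, p=region_probs)
    tss_like = np.isin(regions, ["TSS200", "TSS1500", "5'UTR", "1stExon"])
    island_choices = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
    islands = np.empty(n, dtype=object)
    islands[tss_like] = rng.choice(island_choices, size=int(tss_like.sum()),
                                   p=[0.50, 0.15, 0.15, 0.05, 0.05, 0.10])
    islands[~tss_like] = rng.choice(island_choices, size=int((~tss_like).sum()),
                                    p=[0.10, 0.10, 0.10, 0.12, 0.12, 0.46])
    chroms = rng.integers(1, 23, size=n).astype(str)
    return ProbeManifest(pd.DataFrame({
        "probe_id": probes, "chromosome": chroms, "nearest_gene": nearest,
        "gene_region": regions, "island_region": islands}))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort plus ground truth from a validated config."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    samples = _simulate_samples(cfg, rng)
    frame = samples.frame
    sample_ids = list(frame["sample_id"])
    is_t2d = (frame["group"] == "T2D").to_numpy()
    is_tube = (frame["state"] == "myotube").to_numpy()

    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    probes = [f"cgs{i + 1:07d}" for i in range(cfg.n_probes)]

    de_info, coupled_genes, candidates = _plan_de_genes(cfg, genes, rng)
    truth.de_genes = de_info
    truth.candidate_genes = sorted(candidates)

    expression = _simulate_expression(cfg, genes, samples, de_info, rng)

    # -- probe layout: [coupled | opposite | shared | ngt_only | t2d_only | rest]
    layout = cfg._dynamics_layout()
    n_coupled = len(coupled_genes)
    cursor = n_coupled
    blocks = {}
    for name in ("opposite", "shared", "ngt_only", "t2d_only"):
        blocks[name] = list(range(cursor, cursor + layout[name]))
        cursor += layout[name]
    coupled_probes = probes[:n_coupled]
    truth.coupled_pairs = list(zip(coupled_probes, coupled_genes))
    truth.opposite_probes = [probes[i] for i in blocks["opposite"]]

    manifest = _assign_manifest(cfg, probes, genes, coupled_probes,
                                coupled_genes, rng)

    # -- baseline methylation on the logit scale (bimodal hypo/hyper)
    island = manifest.frame.drop_duplicates("probe_id").set_index("probe_id")
    is_island = (island.loc[probes, "island_region"] == "Island").to_numpy()
    hypo = rng.random(cfg.n_probes) < np.where(is_island, 0.8, 0.3)
    center = np.where(hypo, logit(0.1), logit(0.9)) + rng.normal(0, 0.5, cfg.n_probes)
    dynamic_rows = np.array(blocks["opposite"] + blocks["shared"]
                            + blocks["ngt_only"] + blocks["t2d_only"], dtype=int)
    if dynamic_rows.size:
        # dynamic probes need mid-range baselines so shifts stay in [0, 1]
        center[dynamic_rows] = rng.uniform(logit(0.25), logit(0.75),
                                           dynamic_rows.size)
    beta_logit = center[:, None] + rng.normal(0.0, cfg.beta_noise_logit,
                                              (cfg.n_probes, len(sample_ids)))
    beta = expit(beta_logit)

    # -- negative methylation-expression coupling (additive on logit scale)
    rho = cfg.coupling_strength
    noise_sd = float(np.sqrt(1.0 / rho ** 2 - 1.0)) if rho < 1.0 else 0.0
    gene_index = expression.feature_index
    for row, (probe, gene) in enumerate(truth.coupled_pairs):
        e = expression.values[gene_index[gene]]
        z = (e - e.mean()) / (e.std() or 1.0)
        eps = rng.normal(0.0, noise_sd, z.size) if noise_sd else 0.0
        beta[row] = expit(rng.normal(0.0, 0.5) - z + eps)

    # -- differentiation dynamics (myotube shift per group)
    def shift_rows(rows, group_mask, signs, magnitudes, group_name):
        cols = np.flatnonzero(group_mask & is_tube)
        for r, s, m in zip(rows, signs, magnitudes):
            beta[r, cols] = np.clip(beta[r, cols] + s * m / 100.0, 0.0, 1.0)
            truth.dynamic_probes.setdefault(group_name, {})[probes[r]] = float(s * m)

    mag = lambda k: rng.uniform(cfg.dynamics_shift_lo_pp, cfg.dynamics_shift_hi_pp, k)
    ngt_mask = ~is_t2d
    t2d_mask = is_t2d

    opp = blocks["opposite"]
    half = len(opp) // 2
    opp_signs_ngt = np.array([1.0] * half + [-1.0] * (len(opp) - half))
    opp_mags = mag(len(opp))
    shift_rows(opp, ngt_mask, opp_signs_ngt, opp_mags, "NGT")
    shift_rows(opp, t2d_mask, -opp_signs_ngt, opp_mags, "T2D")

    sh = blocks["shared"]
    sh_signs = rng.choice([-1.0, 1.0], len(sh))
    sh_mags = mag(len(sh))
    shift_rows(sh, ngt_mask, sh_signs, sh_mags, "NGT")
    shift_rows(sh, t2d_mask, sh_signs, sh_mags, "T2D")

    for name, mask, gname in (("ngt_only", ngt_mask, "NGT"),
                              ("t2d_only", t2d_mask, "T2D")):
        rows = blocks[name]
        shift_rows(rows, mask, rng.choice([-1.0, 1.0], len(rows)),
                   mag(len(rows)), gname)

    # -- optional planted open-sea offset in T2D myoblasts
    if cfg.opensea_offset_t2d_pp:
        opensea = (island.loc[probes, "island_region"] == "OpenSea").to_numpy()
        cols = np.flatnonzero(t2d_mask & ~is_tube)
        rows = np.flatnonzero(opensea)
        beta[np.ix_(rows, cols)] = np.clip(
            beta[np.ix_(rows, cols)] + cfg.opensea_offset_t2d_pp / 100.0, 0.0, 1.0)

    beta_matrix = BetaMatrix(tuple(probes), tuple(sample_ids), beta)

    # -- promoters with the motif planted in down-regulated-truth genes
    down_genes = truth.down_gene_ids()
    bases = np.array(list("ACGT"))
    raw = rng.integers(0, 4, size=(cfg.n_genes, cfg.promoter_length))
    promoters = {}
    motif = consensus_motif("PLANTED_MOTIF", cfg.motif_consensus)
    L = len(cfg.motif_consensus)
    for i, gene in enumerate(genes):
        seq = bases[raw[i]]
        frac = cfg.motif_frac_fg if gene in down_genes else cfg.motif_frac_bg
        if rng.random() < frac:
            pos = int(rng.integers(0, cfg.promoter_length - L + 1))
            seq[pos:pos + L] = list(cfg.motif_consensus)
            truth.motif_genes.append(gene)
        promoters[gene] = "".join(seq)

    # -- gene sets: one planted DE-heavy set plus random sets
    de_list = sorted(de_info)
    non_de = [g for g in genes if g not in de_info]
    planted_size = min(50, len(de_list) + len(non_de))
    n_from_de = min(round(0.7 * planted_size), len(de_list))
    planted_members = (list(rng.choice(de_list, n_from_de, replace=False))
                       + list(rng.choice(non_de, planted_size - n_from_de,
                                         replace=False)))
    sets = [GeneSet("PLANTED_DE_SET", "planted: enriched for true effects",
                    frozenset(planted_members))]
    for i in range(cfg.n_random_sets):
        size = int(rng.integers(10, 61))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(f"RANDOM_SET_{i + 1:02d}", "random control set", members))
    truth.enriched_sets = ["PLANTED_DE_SET"]

    # -- term annotation: down-truth genes get denser "autophagy" terms
    vocab = ["autophagy regulation", "muscle fiber development",
             "cardiac muscle morphogenesis", "histone modification",
             "oxidative phosphorylation", "cell cycle arrest",
             "lipid transport", "protein folding"]
    ann_rows = []
    for gene in genes:
        k = int(rng.integers(1, 4))
        weights = np.ones(len(vocab))
        if gene in down_genes:
            weights[0] = 4.0               # enrich the autophagy term
        weights /= weights.sum()
        for term in rng.choice(vocab, size=k, p=weights):
            ann_rows.append((gene, term))
    term_annotation = pd.DataFrame(ann_rows, columns=["gene", "term"])

    bundle = CohortBundle(expression=expression, beta=beta_matrix,
                          manifest=manifest, samples=samples, truth=truth)
    return SimulatedCohort(bundle=bundle, truth=truth,
                           gene_sets=GeneSetCollection.from_sets(sets),
                           promoters=promoters, motif=motif,
                           term_annotation=term_annotation)


def evaluate_calls(truth_ids, call_ids) -> tuple[float, float]:
    """(sensitivity, observed FDR) of a called set against planted truth."""
    truth_ids = set(truth_ids)
    call_ids = set(call_ids)
    sensitivity = len(call_ids & truth_ids) / len(truth_ids) if truth_ids else 0.0
    fdr = len(call_ids - truth_ids) / max(len(call_ids), 1)
    return sensitivity, fdr
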