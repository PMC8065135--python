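"""Gene-set, search-term and promoter-motif enrichment.

Preranked GSEA with gene-set randomisation (random same-size draws from
the ranked universe), keyword-frequency enrichment over GO-style term
annotations with inclusion/exclusion substrings, and PSCAN-style PWM
promoter scanning (best log-odds score per promoter over all offsets and
both strands, z-test of foreground vs background means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm as _norm_dist

from . import stats_core
from .errors import ValidationError
from .formats_io import GeneSetCollection, MotifModel

log = logging.getLogger(__name__)

__all__ = [
    "GSEAResult",
    "gsea_preranked",
    "TermQuery",
    "TermEnrichmentResult",
    "go_searchterm_enrichment",
    "MotifEnrichmentResult",
    "motif_enrichment",
    "log_odds_matrix",
    "best_motif_scores",
]


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr: float
    leading_edge: tuple[str, ...]
    set_size: int


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n_genes: int):
    """Enrichment score(s) from sorted 0-based hit positions.

    ``positions`` is draws x set_size (one row per permutation or the
    observed set).  Hit increments are ``weights[pos]`` normalised per
    row; every miss decrements 1/(N - set_size).  Returns (es, peak_idx)
    where peak_idx is the index into the hit list of the extreme
    (negative peak encoded as -(j+1) for "just before hit j").
    """
    positions = np.atleast_2d(positions)
    m, k = positions.shape
    miss = 1.0 / (n_genes - k)
    w = weights[positions]
    totals = w.sum(axis=1, keepdims=True)
    # a set with all-zero weights degenerates to equal hit increments
    fallback = totals[:, 0] == 0.0
    if fallback.any():
        w = w.copy()
        w[fallback] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / totals
    j = np.arange(1, k + 1)
    at_hit = cum - (positions + 1 - j) * miss          # value just after hit j
    before_hit = np.concatenate(
        [np.zeros((m, 1)), cum[:, :-1]], axis=1) - (positions - (j - 1)) * miss
    hi_idx = np.argmax(at_hit, axis=1)
    lo_idx = np.argmin(before_hit, axis=1)
    hi = at_hit[np.arange(m), hi_idx]
    lo = np.minimum(before_hit[np.arange(m), lo_idx], 0.0)
    es = np.where(hi >= -lo, hi, lo)
    peak = np.where(hi >= -lo, hi_idx, -(lo_idx + 1))
    return es, peak


def gsea_preranked(ranked, sets: GeneSetCollection, n_perm: int = 1000,
                   seed: int = 0, size_range=(1, 500),
                   weight: float = 1.0) -> list[GSEAResult]:
    """Preranked enrichment over an ordered (gene, score) list.

    Null distributions come from ``n_perm`` random same-size gene draws
    per set size (seeded); NES = ES / mean(|null ES| of matching sign);
    nominal p is the fraction of same-sign null ES at least as extreme;
    FDR follows the pooled-NES procedure.  Sets empty after intersection
    with the universe are dropped with a log entry.
    """
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    n_genes = len(genes)
    if n_genes == 0:
        raise ValidationError("ranked list is empty")
    if len(set(genes)) != n_genes:
        raise ValidationError("ranked list contains duplicate genes")
    position = {g: i for i, g in enumerate(genes)}
    absw = np.abs(scores) ** weight
    lo, hi = size_range
    rng = np.random.default_rng(seed)

    kept = []
    for name, gene_set in sets.items():
        pos = np.sort([position[g] for g in gene_set.members if g in position])
        if pos.size == 0:
            log.info("gene set %s empty after intersection; dropped", name)
            continue
        if not (lo <= pos.size <= hi) or pos.size >= n_genes:
            log.info("gene set %s size %d outside [%d, %d]; dropped",
                     name, pos.size, lo, hi)
            continue
        kept.append((name, pos))
    if not kept:
        return []

    null_by_size: dict[int, np.ndarray] = {}
    for _, pos in kept:
        k = pos.size
        if k not in null_by_size:
            draws = np.sort(
                rng.random((n_perm, n_genes)).argpartition(k - 1, axis=1)[:, :k],
                axis=1)
            null_by_size[k], _ = _es_from_positions(draws, absw, n_genes)

    observed = []
    for name, pos in kept:
        es_arr, peak_arr = _es_from_positions(pos[None, :], absw, n_genes)
        es, peak = float(es_arr[0]), int(peak_arr[0])
        null = null_by_size[pos.size]
        if es >= 0:
            same = null[null >= 0]
            extreme = int((same >= es).sum())
            leading = pos[: peak + 1]
        else:
            same = null[null < 0]
            extreme = int((same <= es).sum())
            leading = pos[(-peak - 1):]      # hits from the negative peak on
        p_nom = (extreme + 1) / (same.size + 1)
        mean_same = np.abs(same).mean() if same.size else np.abs(null).mean()
        nes = es / mean_same if mean_same > 0 else 0.0
        observed.append((name, es, float(nes), float(p_nom),
                         tuple(genes[i] for i in leading), pos.size))

    all_nes = np.array([o[2] for o in observed])
    pooled = []
    for size in {o[5] for o in observed}:
        null = null_by_size[size]
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else 1.0
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else 1.0
        denom = np.where(null >= 0, max(pos_mean, 1e-12), max(neg_mean, 1e-12))
        pooled.append(null / denom)
    pooled_null = np.concatenate(pooled)

    results = []
    for name, es, nes, p_nom, leading, size in observed:
        if nes >= 0:
            null_frac_pos = max(float((pooled_null >= 0).mean()), 1e-12)
            null_tail = float((pooled_null >= nes).mean()) / null_frac_pos
            obs_frac_pos = max(float((all_nes >= 0).mean()), 1e-12)
            obs_tail = max(float((all_nes >= nes).mean()) / obs_frac_pos, 1e-12)
        else:
            null_frac_neg = max(float((pooled_null < 0).mean()), 1e-12)
            null_tail = float((pooled_null <= nes).mean()) / null_frac_neg
            obs_frac_neg = max(float((all_nes < 0).mean()), 1e-12)
            obs_tail = max(float((all_nes <= nes).mean()) / obs_frac_neg, 1e-12)
        fdr = min(1.0, null_tail / obs_tail)
        results.append(GSEAResult(set_name=name, es=es, nes=nes,
                                  p_nominal=p_nom, fdr=fdr,
                                  leading_edge=leading, set_size=size))
    return sorted(results, key=lambda r: (r.fdr, r.p_nominal, r.set_name))


def brute_force_es(ranked, members, weight: float = 1.0) -> float:
    """O(N) running-sum enrichment score; the oracle counterpart of the
    hit-position formula used by :func:`gsea_preranked`."""
    scores = np.array([s for _, s in ranked], dtype=float)
    hits = np.array([g in members for g, _ in ranked])
    n = len(ranked)
    k = int(hits.sum())
    if k == 0 or k == n:
        raise ValidationError("set must be a proper non-empty subset")
    w = np.abs(scores) ** weight
    total = w[hits].sum()
    if total == 0:
        w = np.ones_like(w)
        total = float(k)
    running = 0.0
    hi = lo = 0.0
    for i in range(n):
        running += w[i] / total if hits[i] else -1.0 / (n - k)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi if hi >= -lo else lo


# ---------------------------------------------------------------------------
# search-term enrichment over term annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermQuery:
    """Substring query over term names, with exclusion phrases.

    A term matches when it contains any ``include`` substring and still
    contains one after all ``exclude`` phrases are removed (so a term
    mentioning only an excluded phrase does not count).
    """

    name: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def matches(self, term: str) -> bool:
        term = term.lower()
        if not any(sub.lower() in term for sub in self.include):
            return False
        stripped = term
        for phrase in self.exclude:
            stripped = stripped.replace(phrase.lower(), "")
        return any(sub.lower() in stripped for sub in self.include)


@dataclass(frozen=True)
class TermEnrichmentResult:
    query: str
    feature_count: int
    feature_total: int
    universe_count: int
    universe_total: int
    feature_pct: float
    universe_pct: float
    test: stats_core.TestResult | None


def go_searchterm_enrichment(feature_genes, universe, annotation,
                             term_queries) -> list[TermEnrichmentResult]:
    """Term-occurrence frequency of each query in feature genes vs universe.

    ``annotation`` is a (gene, term) table; a gene annotated to several
    matching terms counts once per term.  Frequencies are relative to the
    total term count of the gene group; significance is a 2x2 chi-square
    on matching vs non-matching term occurrences.
    """
    if isinstance(annotation, pd.DataFrame):
        rows = list(zip(annotation.iloc[:, 0].astype(str),
                        annotation.iloc[:, 1].astype(str)))
    else:
        rows = [(str(g), str(t)) for g, t in annotation]
    feature_genes = set(feature_genes)
    universe = set(universe)
    if not feature_genes <= universe:
        raise ValidationError("feature genes must be a subset of the universe")
    feature_rows = [t for g, t in rows if g in feature_genes]
    universe_rows = [t for g, t in rows if g in universe]
    results = []
    for query in term_queries:
        f_match = sum(query.matches(t) for t in feature_rows)
        u_match = sum(query.matches(t) for t in universe_rows)
        f_total, u_total = len(feature_rows), len(universe_rows)
        if u_match == 0:
            log.warning("query %s matches no universe terms", query.name)
            results.append(TermEnrichmentResult(
                query.name, f_match, f_total, u_match, u_total,
                0.0, 0.0, None))
            continue
        table = np.array([[f_match, f_total - f_match],
                          [u_match, u_total - u_match]], dtype=float)
        test = stats_core.chi2_test(table, "independence")
        results.append(TermEnrichmentResult(
            query.name, f_match, f_total, u_match, u_total,
            100.0 * f_match / f_total if f_total else 0.0,
            100.0 * u_match / u_total if u_total else 0.0,
            test))
    return results


# ---------------------------------------------------------------------------
# promoter motif enrichment
# ---------------------------------------------------------------------------

_BASE_INDEX = np.full(128, 0, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def log_odds_matrix(motif: MotifModel) -> np.ndarray:
    """4 x L log2-odds matrix with background-weighted pseudocounts."""
    counts = motif.counts
    totals = counts.sum(axis=0, keepdims=True)
    probs = (counts + motif.pseudocount * motif.background[:, None]) / (
        totals + motif.pseudocount)
    return np.log2(probs / motif.background[:, None])


def _reverse_complement_lom(lom: np.ndarray) -> np.ndarray:
    return lom[::-1, ::-1]


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def best_motif_scores(sequences, motif: MotifModel, batch: int = 256):
    """Best log-odds score per sequence over every offset on both strands.

    ``sequences`` is a list of strings.  Sequences shorter than the
    motif get NaN (callers exclude and log them).
    """
    lom = log_odds_matrix(motif)
    rc = _reverse_complement_lom(lom)
    L = motif.length
    cols = np.arange(L)
    out = np.full(len(sequences), np.nan)
    by_length: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        if len(seq) >= L:
            by_length.setdefault(len(seq), []).append(i)
    for length, idx in by_length.items():
        for start in range(0, len(idx), batch):
            chunk = idx[start:start + batch]
            enc = np.stack([_encode(sequences[i]) for i in chunk])
            windows = sliding_window_view(enc, L, axis=1)
            fwd = lom[windows, cols].sum(axis=2).max(axis=1)
            rev = rc[windows, cols].sum(axis=2).max(axis=1)
            out[chunk] = np.maximum(fwd, rev)
    return out


def relative_scores(best: np.ndarray, motif: MotifModel) -> np.ndarray:
    """Rescale log-odds to [0, 1] between min and max attainable scores."""
    lom = log_odds_matrix(motif)
    smin = lom.min(axis=0).sum()
    smax = lom.max(axis=0).sum()
    if smax == smin:
        return np.ones_like(best)
    return (best - smin) / (smax - smin)


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_name: str
    z: float
    p: float
    mean_best_fg: float
    mean_best_bg: float
    frac_with_motif_fg: float
    frac_with_motif_bg: float
    n_fg: int
    n_bg: int
    n_skipped: int = 0


def motif_enrichment(motif: MotifModel, fg_promoters: dict, bg_promoters: dict,
                     presence_threshold: float = 0.8) -> MotifEnrichmentResult:
    """PSCAN-style motif over-representation in foreground promoters.

    z = (mean_fg - mean_bg) / (sd_bg / sqrt(n_fg)) on best log-odds
    scores, one-sided p (background should be all promoters).  Presence
    fractions use the relative-score threshold and are descriptive.
    """
    fg_names = sorted(fg_promoters)
    bg_names = sorted(bg_promoters)
    fg_best = best_motif_scores([fg_promoters[g] for g in fg_names], motif)
    bg_best = best_motif_scores([bg_promoters[g] for g in bg_names], motif)
    skipped = int(np.isnan(fg_best).sum() + np.isnan(bg_best).sum())
    if skipped:
        log.warning("excluded %d promoter(s) shorter than the motif", skipped)
    fg_best = fg_best[~np.isnan(fg_best)]
    bg_best = bg_best[~np.isnan(bg_best)]
    if fg_best.size == 0 or bg_best.size < 2:
        raise ValidationError("need >= 1 foreground and >= 2 background promoters")
    mean_fg = float(fg_best.mean())
    mean_bg = float(bg_best.mean())
    sd_bg = float(bg_best.std(ddof=1))
    if sd_bg == 0.0:
        z = 0.0 if mean_fg == mean_bg else np.inf * np.sign(mean_fg - mean_bg)
    else:
        z = (mean_fg - mean_bg) / (sd_bg / np.sqrt(fg_best.size))
    p = float(_norm_dist.sf(z))
    fg_rel = relative_scores(fg_best, motif)
    bg_rel = relative_scores(bg_best, motif)
    return MotifEnrichmentResult(
        motif_name=motif.name, z=float(z), p=p,
        mean_best_fg=mean_fg, mean_best_bg=mean_bg,
        frac_with_motif_fg=float((fg_rel >= presence_threshold).mean()),
        frac_with_motif_bg=float((bg_rel >= presence_threshold).mean()),
        n_fg=int(fg_best.size), n_bg=int(bg_best.size), n_skipped=skipped)
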