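"""Gene set enrichment analysis: weighted running-sum ES with permutation
significance.

This is a from-scratch implementation of the classic two-class GSEA
procedure:

1. rank all genes by the signal-to-noise ratio between the two sample
   classes, ``(mean_A - mean_B) / (sd_A + sd_B)`` with each sd floored at
   ``0.2 * |class mean|`` (absolute floor for zero means);
2. walk the ranked list: a gene in the set ("hit") adds
   ``|r_i|^p / sum_hits |r_j|^p``, a miss subtracts ``1 / (N - N_hits)``;
   the enrichment score ES is the signed maximum deviation of this running
   sum from zero (the sum returns exactly to zero at the end);
3. significance by permutation — phenotype mode reshuffles the class labels
   and re-ranks (enumerating all distinct assignments when few enough),
   gene_set mode draws random same-size sets; the nominal p is the
   same-signed tail of the permutation ES distribution, the normalized
   enrichment score NES divides ES by the mean same-signed permutation ES,
   and FDR q / FWER p are computed across the whole set collection from the
   pooled null NES distribution.

An estimated p of 0 is reported as 0.0 with a resolution floor
``1 / n_permutations`` recorded alongside, matching the usual "q = 0.0"
display convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ExpressionMatrix

__all__ = [
    "RankedGeneList",
    "GeneSet",
    "PermutationConfig",
    "EnrichmentResult",
    "signal_to_noise",
    "rank_genes",
    "compute_es",
    "permutation_significance",
]


@dataclass
class RankedGeneList:
    """Gene ids ordered by descending ranking metric."""

    ids: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.ids.shape != self.metric.shape:
            raise ValueError("ids and metric must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("ranked gene ids must be unique")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be non-increasing along the ranking")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class GeneSet:
    """A named set of gene ids."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings.

    ``weight_exponent`` is the hit-weight power p (p=0 gives the classic
    unweighted Kolmogorov–Smirnov statistic; p=1, the default, weights hits
    by their metric).  ``min_size``/``max_size`` restrict analysed sets after
    intersection with the ranked universe.
    """

    n_permutations: int = 1000
    mode: str = "phenotype"
    weight_exponent: float = 1.0
    min_size: int = 15
    max_size: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1, got %r" % (self.n_permutations,))
        if self.mode not in ("phenotype", "gene_set"):
            raise ValueError("mode must be 'phenotype' or 'gene_set', got %r" % (self.mode,))
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0, got %r" % (self.weight_exponent,))


@dataclass
class EnrichmentResult:
    """Per-set enrichment outcome with its running-sum walk."""

    name: str
    size: int
    es: float
    nes: float
    p: float
    fdr_q: float
    fwer_p: float
    running_sum: np.ndarray
    hit_positions: np.ndarray
    p_floor: float

    def to_dict(self) -> dict:
        return {"name": self.name, "size": self.size, "es": self.es,
                "nes": self.nes, "p": self.p, "fdr_q": self.fdr_q,
                "fwer_p": self.fwer_p, "p_floor": self.p_floor}


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _s2n_from_arrays(a: np.ndarray, b: np.ndarray, abs_floor: float,
                     rel_floor: float) -> np.ndarray:
    """Signal-to-noise per row of two genes x samples arrays."""
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa = a.std(axis=1, ddof=1)
    sb = b.std(axis=1, ddof=1)
    fa = np.where(ma != 0, rel_floor * np.abs(ma), abs_floor)
    fb = np.where(mb != 0, rel_floor * np.abs(mb), abs_floor)
    sa = np.maximum(sa, np.maximum(fa, 0.0))
    sb = np.maximum(sb, np.maximum(fb, 0.0))
    return (ma - mb) / (sa + sb)


def signal_to_noise(matrix: ExpressionMatrix, classes: pd.Series,
                    class_a: str, class_b: str,
                    rel_floor: float = 0.2, abs_floor: float = 0.2) -> pd.Series:
    """Per-gene signal-to-noise ratio between two sample classes.

    ``classes`` maps sample id -> class label.  Each class sd is floored at
    ``rel_floor * |class mean|`` (``abs_floor`` when the mean is 0), so a
    gene constant in all samples scores exactly 0 rather than 0/0.
    """
    sa = [s for s in matrix.values.columns if classes.get(s) == class_a]
    sb = [s for s in matrix.values.columns if classes.get(s) == class_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each class needs >= 2 samples (got %d vs %d)" % (len(sa), len(sb)))
    out = _s2n_from_arrays(matrix.values[sa].to_numpy(dtype=float),
                           matrix.values[sb].to_numpy(dtype=float),
                           abs_floor, rel_floor)
    return pd.Series(out, index=matrix.values.index, name="signal_to_noise")


def rank_genes(metric: pd.Series) -> RankedGeneList:
    """Order genes by descending metric; ties keep original gene order."""
    order = np.argsort(-metric.to_numpy(), kind="stable")
    return RankedGeneList(ids=metric.index.to_numpy()[order],
                          metric=metric.to_numpy()[order])


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def _walk(metric_ranked: np.ndarray, hit: np.ndarray, p_w: float) -> np.ndarray:
    """Running sum over a ranked list given a boolean hit mask."""
    n = len(metric_ranked)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    if n_hit == n:
        raise ValueError("gene set equals the ranked universe; miss decrement undefined")
    w = np.abs(metric_ranked) ** p_w
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all hit metrics exactly 0 -> fall back to equal weights
        inc = hit / n_hit
    else:
        inc = w_hit / total
    dec = (~hit) / (n - n_hit)
    return np.cumsum(inc - dec)


def compute_es(ranked: RankedGeneList, gene_set, p_w: float = 1.0
               ) -> tuple[float, np.ndarray, np.ndarray]:
    """Enrichment score of one gene set against a ranked list.

    Returns ``(es, running_sum, hit_positions)``; ES is the running-sum
    value of largest absolute magnitude (signed).
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    hit = np.isin(ranked.ids, list(members))
    walk = _walk(ranked.metric, hit, p_w)
    es = float(walk[np.argmax(np.abs(walk))])
    return es, walk, np.flatnonzero(hit)


def _es_only(metric_ranked: np.ndarray, hit: np.ndarray, p_w: float) -> float:
    walk = _walk(metric_ranked, hit, p_w)
    return float(walk[np.argmax(np.abs(walk))])


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def _phenotype_label_matrix(classes: np.ndarray, class_a: str, n_perm: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Boolean matrix (perms x samples): True where the sample plays class A.

    Enumerates all distinct assignments of the class-A slots when their
    count is <= n_perm, otherwise samples label shuffles at random.
    """
    n = len(classes)
    n_a = int((classes == class_a).sum())
    n_distinct = math.comb(n, n_a)
    if n_distinct <= n_perm:
        out = np.zeros((n_distinct, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n_a)):
            out[i, list(combo)] = True
        return out
    out = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        out[i, rng.permutation(n)[:n_a]] = True
    return out


def permutation_significance(matrix: ExpressionMatrix, classes: pd.Series,
                             gene_sets: list[GeneSet],
                             class_a: str, class_b: str,
                             config: PermutationConfig = PermutationConfig()
                             ) -> list[EnrichmentResult]:
    """Full GSEA for a collection of gene sets with permutation statistics.

    Sets are restricted to the ranked universe and filtered by
    ``min_size``/``max_size`` (filtered-out sets are skipped with a
    warning).  See the module docstring for the nominal p / NES / FDR /
    FWER definitions.
    """
    rng = np.random.default_rng(config.seed)
    p_w = config.weight_exponent

    sample_ids = [s for s in matrix.values.columns
                  if classes.get(s) in (class_a, class_b)]
    labels = np.array([classes[s] for s in sample_ids])
    x = matrix.values[sample_ids].to_numpy(dtype=float)
    if (labels == class_a).sum() < 2 or (labels == class_b).sum() < 2:
        raise ValueError("phenotype permutation requires >= 2 samples per class")

    gene_ids = matrix.values.index.to_numpy()
    metric = _s2n_from_arrays(x[:, labels == class_a], x[:, labels == class_b],
                              0.2, 0.2)
    order = np.argsort(-metric, kind="stable")
    ranked = RankedGeneList(ids=gene_ids[order], metric=metric[order])

    kept: list[tuple[GeneSet, np.ndarray]] = []   # (set, membership mask over genes)
    for gs in gene_sets:
        mask = np.isin(gene_ids, list(gs.members))
        size = int(mask.sum())
        if size < config.min_size or size > config.max_size:
            warnings.warn("gene set %r (size %d in universe) outside [%d, %d]; skipped"
                          % (gs.name, size, config.min_size, config.max_size),
                          RuntimeWarning, stacklevel=2)
            continue
        if size == len(gene_ids):
            warnings.warn("gene set %r equals the universe; skipped" % gs.name,
                          RuntimeWarning, stacklevel=2)
            continue
        kept.append((gs, mask))
    if not kept:
        return []

    observed = []
    for gs, mask in kept:
        es, walk, hits = compute_es(ranked, gs, p_w=p_w)
        observed.append((es, walk, hits))

    # --- permutation null ES matrix (n_perm x n_sets) ---
    if config.mode == "phenotype":
        amat = _phenotype_label_matrix(labels, class_a, config.n_permutations, rng)
        n_perm = amat.shape[0]
        perm_es = np.empty((n_perm, len(kept)))
        for i in range(n_perm):
            sel = amat[i]
            m = _s2n_from_arrays(x[:, sel], x[:, ~sel], 0.2, 0.2)
            o = np.argsort(-m, kind="stable")
            m_sorted = m[o]
            for j, (_, mask) in enumerate(kept):
                perm_es[i, j] = _es_only(m_sorted, mask[o], p_w)
    else:  # gene_set mode: random same-size sets against the observed ranking
        n_perm = config.n_permutations
        perm_es = np.empty((n_perm, len(kept)))
        hit_sorted = {j: mask[order] for j, (_, mask) in enumerate(kept)}
        n_genes = len(gene_ids)
        for j, (_, mask) in enumerate(kept):
            size = int(hit_sorted[j].sum())
            for i in range(n_perm):
                idx = rng.choice(n_genes, size=size, replace=False)
                h = np.zeros(n_genes, dtype=bool)
                h[idx] = True
                perm_es[i, j] = _es_only(ranked.metric, h, p_w)

    # --- per-set nominal p and NES ---
    results = []
    nes_obs = np.empty(len(kept))
    nes_null_cols = []
    for j, (gs, mask) in enumerate(kept):
        es = observed[j][0]
        col = perm_es[:, j]
        pos, neg = col[col >= 0], col[col < 0]
        if es >= 0:
            denom = max(len(pos), 1)
            p_nom = float((pos >= es).sum()) / denom
            mean_same = pos.mean() if len(pos) else np.nan
        else:
            denom = max(len(neg), 1)
            p_nom = float((neg <= es).sum()) / denom
            mean_same = np.abs(neg).mean() if len(neg) else np.nan
        nes = es / mean_same if mean_same and not np.isnan(mean_same) else np.nan
        nes_obs[j] = nes
        # normalized null: each permutation ES divided by the matching-sign mean
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        null_nes = np.where(col >= 0, col / mean_pos, col / mean_neg)
        nes_null_cols.append(null_nes[~np.isnan(null_nes)])
        results.append([gs, es, p_nom])

    pooled = np.concatenate(nes_null_cols) if nes_null_cols else np.array([])

    # FWER null: per permutation, the most extreme normalized ES on each side
    null_nes_mat = np.full((perm_es.shape[0], len(kept)), np.nan)
    for j in range(len(kept)):
        col = perm_es[:, j]
        pos, neg = col[col >= 0], col[col < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        null_nes_mat[:, j] = np.where(col >= 0, col / mean_pos, col / mean_neg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_pos = np.nanmax(np.where(null_nes_mat >= 0, null_nes_mat, np.nan), axis=1)
        min_neg = np.nanmin(np.where(null_nes_mat < 0, null_nes_mat, np.nan), axis=1)

    out: list[EnrichmentResult] = []
    p_floor = 1.0 / perm_es.shape[0]
    for j, (gs, es, p_nom) in enumerate(results):
        nes = nes_obs[j]
        if np.isnan(nes):
            q = 1.0
            fwer = 1.0
        elif nes >= 0:
            num = (pooled >= nes).mean() if len(pooled) else 1.0
            den = (nes_obs >= nes).mean()
            q = min(num / den, 1.0) if den > 0 else 1.0
            fwer = float(np.nanmean(max_pos >= nes)) if np.isfinite(max_pos).any() else 1.0
        else:
            num = (pooled <= nes).mean() if len(pooled) else 1.0
            den = (nes_obs <= nes).mean()
            q = min(num / den, 1.0) if den > 0 else 1.0
            fwer = float(np.nanmean(min_neg <= nes)) if np.isfinite(min_neg).any() else 1.0
        es_val, walk, hits = observed[j]
        out.append(EnrichmentResult(
            name=gs.name, size=int(np.isin(gene_ids, list(gs.members)).sum()),
            es=es_val, nes=float(nes), p=p_nom, fdr_q=float(q),
            fwer_p=float(fwer), running_sum=walk, hit_positions=hits,
            p_floor=p_floor))
    return out
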