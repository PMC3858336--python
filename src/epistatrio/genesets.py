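"""Fold-change classification of c-Myb-responsive genes and KIX sensitivity.

The filtering pipeline mirrors the microarray analyses of c-Myb
overexpression in wild-type vs KIX-mutant fibroblasts: replicate log2
signals are averaged per condition, probes below a detection floor are
dropped, genes induced at least ``induce_ratio``-fold (default 2) by c-Myb
are called activated and genes reduced to at most ``repress_ratio`` of
control (default 0.5) are called repressed.  A regulated gene is
KIX-sensitive when its c-Myb response is at least ``sensitivity_ratio``-fold
(default 1.5) weaker in the KIX mutant — i.e. WT/mutant signal ratio >= 1.5
for activated genes and mutant/WT >= 1.5 for repressed genes.  All
thresholds are inclusive.  Ratios are computed from averaged log2 signals
(differences of means of logs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ExpressionMatrix

__all__ = [
    "FilterParams",
    "GeneSetResult",
    "ConcordanceResult",
    "average_replicates",
    "presence_filter",
    "classify_myb_response",
    "classify_myb_response_replicates",
    "kix_sensitivity",
    "direction_concordance",
    "collapse_probes_to_genes",
    "ttest_filter",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the expression-filtering pipeline (all inclusive).

    ``presence_floor`` is on the log2-signal scale (3.4 = twice a typical
    array background); the ratio thresholds are linear-scale fold changes.
    ``p_threshold`` applies only when a replicate-level t-test filter is
    explicitly requested.
    """

    presence_floor: float = 3.4
    induce_ratio: float = 2.0
    repress_ratio: float = 0.5
    sensitivity_ratio: float = 1.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.induce_ratio <= 1:
            raise ValueError("induce_ratio must be > 1, got %r" % (self.induce_ratio,))
        if not 0 < self.repress_ratio < 1:
            raise ValueError("repress_ratio must be in (0, 1), got %r" % (self.repress_ratio,))
        if self.sensitivity_ratio < 1:
            raise ValueError("sensitivity_ratio must be >= 1, got %r" % (self.sensitivity_ratio,))
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1], got %r" % (self.p_threshold,))


@dataclass
class GeneSetResult:
    """Activated/repressed sets with their KIX-sensitive subsets.

    Fractions are |subset| / |parent|; ``None`` when the parent is empty.
    ``ratios`` holds the per-gene linear-scale WT/mutant (activated) or
    mutant/WT (repressed) ratios actually used.
    """

    activated: pd.Index
    repressed: pd.Index
    kix_sensitive_activated: pd.Index
    kix_sensitive_repressed: pd.Index
    frac_sensitive_activated: float | None
    frac_sensitive_repressed: float | None
    ratios: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.kix_sensitive_activated.isin(self.activated).all():
            raise ValueError("kix_sensitive_activated is not a subset of activated")
        if not self.kix_sensitive_repressed.isin(self.repressed).all():
            raise ValueError("kix_sensitive_repressed is not a subset of repressed")


@dataclass
class ConcordanceResult:
    """Overlap and direction agreement between two signed gene lists."""

    n_overlap: int
    n_same_direction: int
    frac_of_a: float | None
    frac_of_overlap: float | None
    table: pd.DataFrame


def average_replicates(matrix: ExpressionMatrix,
                       by: tuple[str, ...] = ("genotype", "treatment")
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Arithmetic mean of log2 signals per gene per condition.

    Conditions are the distinct combinations of the ``by`` annotation
    columns, labelled ``"value1:value2"``.  Returns ``(means, n_replicates)``
    with one column / entry per condition.
    """
    for col in by:
        if col not in matrix.samples.columns:
            raise KeyError("annotation column %r not present" % (col,))
    key = matrix.samples.loc[list(matrix.values.columns), list(by)].astype(str).agg(":".join, axis=1)
    means = matrix.values.T.groupby(key.to_numpy()).mean().T
    counts = key.value_counts()
    empty = counts[counts < 1]
    if len(empty):
        raise ValueError("condition(s) with no samples: %s" % list(empty.index))
    return means, counts.reindex(means.columns)


def presence_filter(means: pd.DataFrame, conditions: list[str],
                    floor: float = 3.4) -> pd.Index:
    """Genes whose mean log2 signal is >= ``floor`` in EVERY named condition.

    The boundary is inclusive: a signal exactly at the floor is retained
    ("below" the floor is what gets excluded).
    """
    missing = [c for c in conditions if c not in means.columns]
    if missing:
        raise KeyError("condition(s) not present: %s" % missing)
    if not conditions:
        return means.index
    keep = (means[list(conditions)] >= floor).all(axis=1)
    return means.index[keep]


def classify_myb_response(means: pd.DataFrame, control: str, treated: str,
                          params: FilterParams = FilterParams(),
                          genes: pd.Index | None = None
                          ) -> tuple[pd.Index, pd.Index, pd.Series]:
    """Activated / repressed calls from the treated-vs-control fold change.

    The linear-scale ratio is ``r = 2**(treated - control)`` on averaged log2
    signals; a gene is activated iff ``r >= induce_ratio`` and repressed iff
    ``r <= repress_ratio`` (both inclusive, hence disjoint).  ``genes``
    optionally restricts to a presence-filtered universe.  Returns
    ``(activated, repressed, ratios)``.
    """
    if control == treated:
        raise ValueError("control and treated conditions are identical (%r)" % (control,))
    for c in (control, treated):
        if c not in means.columns:
            raise KeyError("condition %r not present" % (c,))
    sub = means if genes is None else means.loc[genes]
    ratio = np.power(2.0, sub[treated] - sub[control]).rename("ratio")
    activated = sub.index[ratio >= params.induce_ratio]
    repressed = sub.index[ratio <= params.repress_ratio]
    return activated, repressed, ratio


def classify_myb_response_replicates(matrix: ExpressionMatrix,
                                     control_samples: list[str],
                                     treated_samples: list[str],
                                     params: FilterParams = FilterParams(),
                                     genes: pd.Index | None = None
                                     ) -> tuple[pd.Index, pd.Index]:
    """Stricter fold-change calls requiring the threshold in every replicate.

    Each treated replicate is compared against the control-condition mean;
    a gene is activated (repressed) only if every treated replicate clears
    the inclusive threshold.  This is the conservative reading of a
    "fold-change in both replicates" criterion; :func:`classify_myb_response`
    on averaged signals is the default pipeline mode.
    """
    if set(control_samples) & set(treated_samples):
        raise ValueError("control and treated sample lists overlap")
    ctrl_mean = matrix.values[list(control_samples)].mean(axis=1)
    diffs = matrix.values[list(treated_samples)].sub(ctrl_mean, axis=0)
    if genes is not None:
        diffs = diffs.loc[genes]
    ratios = np.power(2.0, diffs)
    activated = diffs.index[(ratios >= params.induce_ratio).all(axis=1)]
    repressed = diffs.index[(ratios <= params.repress_ratio).all(axis=1)]
    return activated, repressed


def kix_sensitivity(activated: pd.Index, repressed: pd.Index,
                    means: pd.DataFrame, wt_treated: str, mutant_treated: str,
                    params: FilterParams = FilterParams()) -> GeneSetResult:
    """KIX-sensitive subsets of the activated and repressed sets.

    An activated gene is sensitive iff its WT/mutant signal ratio (both
    under c-Myb) is >= ``sensitivity_ratio``; a repressed gene iff the
    mutant/WT ratio is.  Empty parent sets give an absent (None) fraction.
    """
    for c in (wt_treated, mutant_treated):
        if c not in means.columns:
            raise KeyError("condition %r not present" % (c,))
    diff = means[wt_treated] - means[mutant_treated]  # log2(WT / mutant)
    act_ratio = np.power(2.0, diff.loc[activated])
    rep_ratio = np.power(2.0, -diff.loc[repressed])
    sens_act = act_ratio.index[act_ratio >= params.sensitivity_ratio]
    sens_rep = rep_ratio.index[rep_ratio >= params.sensitivity_ratio]
    ratios = pd.concat([
        pd.DataFrame({"ratio": act_ratio, "parent": "activated"}),
        pd.DataFrame({"ratio": rep_ratio, "parent": "repressed"}),
    ])
    return GeneSetResult(
        activated=activated, repressed=repressed,
        kix_sensitive_activated=sens_act, kix_sensitive_repressed=sens_rep,
        frac_sensitive_activated=len(sens_act) / len(activated) if len(activated) else None,
        frac_sensitive_repressed=len(sens_rep) / len(repressed) if len(repressed) else None,
        ratios=ratios)


def direction_concordance(list_a: pd.Series, list_b: pd.Series) -> ConcordanceResult:
    """Overlap and direction agreement between two signed gene lists.

    Each list is a Series mapping gene id -> direction ("up" or "down");
    duplicate ids are rejected.  ``frac_of_a`` is n_overlap / |A|;
    ``frac_of_overlap`` is n_same_direction / n_overlap.
    """
    for name, s in (("A", list_a), ("B", list_b)):
        if s.index.duplicated().any():
            raise ValueError("signed gene list %s has duplicate gene ids" % name)
        bad = set(s.unique()) - {"up", "down"}
        if bad:
            raise ValueError("list %s has invalid direction(s): %s" % (name, sorted(bad)))
    shared = list_a.index.intersection(list_b.index)
    same = shared[(list_a.loc[shared] == list_b.loc[shared]).to_numpy()]
    table = pd.DataFrame({
        "direction_a": list_a.loc[shared],
        "direction_b": list_b.loc[shared],
        "concordant": list_a.loc[shared].to_numpy() == list_b.loc[shared].to_numpy(),
    })
    n_ov, n_same = len(shared), len(same)
    return ConcordanceResult(
        n_overlap=n_ov, n_same_direction=n_same,
        frac_of_a=n_ov / len(list_a) if len(list_a) else None,
        frac_of_overlap=n_same / n_ov if n_ov else None,
        table=table)


def collapse_probes_to_genes(values: pd.DataFrame,
                             probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to genes.

    Keeps, per gene, the probe with the highest mean signal across all
    samples; ties broken lexicographically by probe id.  Probes without a
    gene assignment are dropped.
    """
    mapped = probe_to_gene.reindex(values.index).dropna()
    sub = values.loc[mapped.index]
    score = sub.mean(axis=1)
    order = pd.DataFrame({"gene": mapped, "score": score, "probe": sub.index})
    order = order.sort_values(["gene", "score", "probe"],
                              ascending=[True, False, True], kind="stable")
    best = order.drop_duplicates("gene")["probe"]
    out = sub.loc[best]
    out.index = order.drop_duplicates("gene")["gene"].to_numpy()
    out.index.name = "gene_id"
    return out.sort_index()


def ttest_filter(matrix: ExpressionMatrix, samples_a: list[str],
                 samples_b: list[str], p_threshold: float = 0.05) -> pd.Index:
    """Genes with unadjusted two-sample t-test p < threshold between groups.

    Operates on replicate-level log2 signals (Welch off: equal-variance
    t-test, the classic array-filter convention); strict inequality.
    """
    from scipy import stats

    a = matrix.values[list(samples_a)].to_numpy(dtype=float)
    b = matrix.values[list(samples_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for the t-test")
    _, p = stats.ttest_ind(a, b, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    return matrix.values.index[p < p_threshold]
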