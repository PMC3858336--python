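"""Synthetic data generators for the epistasis and expression pipelines.

Two generators are provided:

* :func:`simulate_blood_counts` draws per-animal blood-cell counts under the
  exact model the epistasis estimator assumes: on the natural-log scale each
  count is a genotype mean plus a per-experiment random intercept (machine
  drift between independent CBC runs) plus residual noise.  Counts are
  returned on the natural scale, so they are lognormal.
* :func:`simulate_expression` builds a log2 expression matrix for a
  two-genotype (wild type vs KIX-mutant) by two-treatment (control vs c-Myb
  overexpression) design with planted activated, repressed and KIX-sensitive
  genes, so the fold-change classifiers and the enrichment machinery can be
  checked against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPE_ROLES",
    "BloodSimConfig",
    "BloodCountDataset",
    "ExprSimConfig",
    "ExpressionMatrix",
    "simulate_blood_counts",
    "simulate_expression",
]

#: The four genotype roles of the complex-haploinsufficiency design:
#: wild type; c-Myb heterozygous null; CBP-KIX/p300-KIX double heterozygote;
#: triple heterozygote.
GENOTYPE_ROLES = ("WT0", "CM1", "CP2", "TH3")

#: Columns every blood-count table carries besides the phenotypes.
ID_COLUMNS = ("animal_id", "genotype", "experiment_id", "strain", "age_months")

PerPhenotype = Union[float, Mapping[str, float]]


# ---------------------------------------------------------------------------
# Blood counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodSimConfig:
    """Generative parameters for a four-genotype blood-count experiment.

    Effect parameters (``baseline_log_mean``, ``delta_cm1``, ``delta_cp2``,
    ``true_E``) may each be a single float (one phenotype named
    ``phenotype``) or a mapping from phenotype name to value, enabling
    multi-cell-type panels.  All effects are on the natural-log scale.  The
    group log-means are constructed so that

        mu_TH3 = baseline + delta_cm1 + delta_cp2 + true_E,

    hence ``true_E = (mu_WT0 + mu_TH3) - (mu_CM1 + mu_CP2)`` exactly.
    """

    n_per_group: int = 15
    n_experiments: int = 5
    baseline_log_mean: PerPhenotype = math.log(1000.0)
    delta_cm1: PerPhenotype = 0.0
    delta_cp2: PerPhenotype = 0.0
    true_E: PerPhenotype = 0.0
    batch_sd: float = 0.1
    residual_sd: float = 0.2
    phenotype: str = "platelets"
    balanced: bool = True
    strain: str = "B6x129F1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1, got %r" % (self.n_per_group,))
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1, got %r" % (self.n_experiments,))
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0, got %r" % (self.batch_sd,))
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0, got %r" % (self.residual_sd,))

    def phenotype_means(self) -> dict[str, dict[str, float]]:
        """Per-phenotype log-scale genotype means, role -> mean."""
        names: list[str] = []
        for f in (self.baseline_log_mean, self.delta_cm1, self.delta_cp2, self.true_E):
            if isinstance(f, Mapping):
                for k in f:
                    if k not in names:
                        names.append(k)
        if not names:
            names = [self.phenotype]

        def val(f: PerPhenotype, name: str, what: str) -> float:
            if isinstance(f, Mapping):
                if what == "baseline_log_mean" and name not in f:
                    raise ValueError(
                        "baseline_log_mean missing phenotype %r" % (name,)
                    )
                return float(f.get(name, 0.0))
            return float(f)

        out = {}
        for name in names:
            base = val(self.baseline_log_mean, name, "baseline_log_mean")
            d1 = val(self.delta_cm1, name, "delta_cm1")
            d2 = val(self.delta_cp2, name, "delta_cp2")
            e = val(self.true_E, name, "true_E")
            out[name] = {
                "WT0": base,
                "CM1": base + d1,
                "CP2": base + d2,
                "TH3": base + d1 + d2 + e,
            }
        return out


@dataclass
class BloodCountDataset:
    """Per-animal phenotype records with genotype and experiment labels.

    ``frame`` holds one row per animal with the identifier columns of
    :data:`ID_COLUMNS` followed by one positive numeric column per phenotype
    (counts in K/uL, or % for hematocrit).  ``metadata`` records at least the
    log base used downstream (natural log throughout this package).
    """

    frame: pd.DataFrame
    phenotypes: tuple[str, ...]
    metadata: dict = field(default_factory=lambda: {"log_base": "e"})

    def __post_init__(self) -> None:
        missing = [c for c in ("animal_id", "genotype", "experiment_id") if c not in self.frame.columns]
        if missing:
            raise ValueError("blood-count table missing required column(s): %s" % ", ".join(missing))
        if self.frame["animal_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["animal_id"].duplicated(), "animal_id"].tolist()
            raise ValueError("duplicate animal_id: %s" % dupes[:5])
        for p in self.phenotypes:
            if p not in self.frame.columns:
                raise ValueError("phenotype column %r not in table" % (p,))
            vals = pd.to_numeric(self.frame[p], errors="coerce")
            if vals.isna().any():
                bad = self.frame.loc[vals.isna(), "animal_id"].tolist()
                raise ValueError("non-numeric %s value for animal(s) %s" % (p, bad[:5]))
            # positivity (needed for the log transform) is enforced at the
            # point of use so that an explicit offset can rescue zeros

    def __len__(self) -> int:
        return len(self.frame)


def _allocate_experiments(n: int, n_experiments: int, balanced: bool,
                          rng: np.random.Generator) -> np.ndarray:
    """Experiment index for each of ``n`` animals of one genotype."""
    if balanced:
        # floor(n / n_exp) per experiment, remainder round-robin
        return np.arange(n) % n_experiments
    return rng.integers(0, n_experiments, size=n)


def simulate_blood_counts(config: BloodSimConfig) -> BloodCountDataset:
    """Draw a four-genotype blood-count dataset under the lognormal model.

    For each animal, ``log(count) = mu_genotype + b_experiment + eps`` with
    ``b ~ N(0, batch_sd^2)`` drawn once per (experiment, phenotype) and
    ``eps ~ N(0, residual_sd^2)`` per animal and phenotype.  Genotypes are
    spread evenly over experiments by default (remainder round-robin);
    ``balanced=False`` assigns experiments at random.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    means = config.phenotype_means()
    phenotypes = tuple(means)

    rows: dict[str, list] = {c: [] for c in ID_COLUMNS}
    exp_idx_all: list[int] = []
    counter = 0
    for role in GENOTYPE_ROLES:
        exp_idx = _allocate_experiments(config.n_per_group, config.n_experiments,
                                        config.balanced, rng)
        for e in exp_idx:
            counter += 1
            rows["animal_id"].append("A%04d" % counter)
            rows["genotype"].append(role)
            rows["experiment_id"].append("E%02d" % (e + 1))
            rows["strain"].append(config.strain)
            exp_idx_all.append(int(e))
    n_total = counter
    rows["age_months"] = np.round(rng.uniform(1.0, 2.0, size=n_total), 2).tolist()

    frame = pd.DataFrame(rows)
    exp_idx_arr = np.asarray(exp_idx_all)
    for p in phenotypes:
        batch = rng.normal(0.0, config.batch_sd, size=config.n_experiments)
        eps = rng.normal(0.0, config.residual_sd, size=n_total)
        mu = frame["genotype"].map(means[p]).to_numpy(dtype=float)
        frame[p] = np.exp(mu + batch[exp_idx_arr] + eps)

    meta = {
        "log_base": "e",
        "true_E": {p: means[p]["WT0"] + means[p]["TH3"] - means[p]["CM1"] - means[p]["CP2"]
                   for p in phenotypes},
        "batch_sd": config.batch_sd,
        "residual_sd": config.residual_sd,
        "seed": config.seed,
    }
    return BloodCountDataset(frame=frame, phenotypes=phenotypes, metadata=meta)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimConfig:
    """Generative parameters for a two-genotype x two-treatment log2 matrix.

    Genes are partitioned into disjoint classes: ``absent`` (signal pinned
    below ``presence_floor``), ``activated`` (treated condition higher by
    ``activation_log2fc``), ``repressed`` (lower by ``|repression_log2fc|``)
    and ``null``.  Within each regulated class a fraction
    ``frac_kix_sensitive`` has its treatment effect attenuated to zero in the
    mutant genotype; the rest respond equally in both genotypes.
    ``gene_sd`` spreads per-gene baselines around ``baseline_log2_mean``;
    regulated-gene baselines are kept high enough that the presence filter
    cannot silently drop a planted gene.
    """

    n_genes: int = 5000
    n_replicates: int = 2
    frac_activated: float = 0.05
    frac_repressed: float = 0.03
    activation_log2fc: float = 2.0
    repression_log2fc: float = -2.0
    frac_kix_sensitive: float = 0.7
    frac_absent: float = 0.1
    baseline_log2_mean: float = 7.0
    gene_sd: float = 1.5
    noise_sd: float = 0.25
    presence_floor: float = 3.4
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("frac_activated", "frac_repressed", "frac_kix_sensitive", "frac_absent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError("%s must be in [0, 1], got %r" % (name, v))
        if self.frac_activated + self.frac_repressed + self.frac_absent > 1.0:
            raise ValueError("frac_activated + frac_repressed + frac_absent must be <= 1")
        if self.activation_log2fc <= 0:
            raise ValueError("activation_log2fc must be > 0, got %r" % (self.activation_log2fc,))
        if self.repression_log2fc >= 0:
            raise ValueError("repression_log2fc must be < 0, got %r" % (self.repression_log2fc,))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0, got %r" % (self.noise_sd,))
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1, got %r" % (self.n_genes,))
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1, got %r" % (self.n_replicates,))


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 signals with per-sample annotations.

    ``values``: DataFrame indexed by gene id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns ``genotype``,
    ``treatment``, ``replicate``.  ``truth`` (optional): per-gene planted
    labels with columns ``status`` in {activated, repressed, null, absent}
    and boolean ``kix_sensitive``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unannotated = [s for s in self.values.columns if s not in self.samples.index]
        if unannotated:
            raise ValueError("samples without annotation: %s" % unannotated[:5])

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.values.columns)


def simulate_expression(config: ExprSimConfig) -> ExpressionMatrix:
    """Simulate a WT/KIX-mutant x control/c-Myb log2 matrix with planted truth.

    Condition means per gene follow the class structure of
    :class:`ExprSimConfig`; i.i.d. N(0, noise_sd^2) log2 noise is added per
    replicate.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array(["g%05d" % (i + 1) for i in range(n)])

    n_abs = int(round(config.frac_absent * n))
    n_act = int(round(config.frac_activated * n))
    n_rep = int(round(config.frac_repressed * n))
    status = np.array(["null"] * n, dtype=object)
    # fixed layout: activated first, then repressed, then absent — callers
    # needing randomized positions can permute gene ids afterwards
    status[:n_act] = "activated"
    status[n_act:n_act + n_rep] = "repressed"
    status[n_act + n_rep:n_act + n_rep + n_abs] = "absent"

    kix = np.zeros(n, dtype=bool)
    n_act_sens = int(round(config.frac_kix_sensitive * n_act))
    n_rep_sens = int(round(config.frac_kix_sensitive * n_rep))
    kix[:n_act_sens] = True
    kix[n_act:n_act + n_rep_sens] = True

    baseline = config.baseline_log2_mean + rng.normal(0.0, config.gene_sd, size=n)
    regulated = (status == "activated") | (status == "repressed")
    # keep planted regulated genes comfortably above the presence floor in
    # every condition, including after repression
    min_base = config.presence_floor + max(1.0, abs(config.repression_log2fc) + 0.5,
                                           config.activation_log2fc + 0.5)
    baseline[regulated] = np.maximum(baseline[regulated], min_base)
    baseline[status == "absent"] = config.presence_floor - 1.5

    effect = np.zeros(n)
    effect[status == "activated"] = config.activation_log2fc
    effect[status == "repressed"] = config.repression_log2fc

    cols: dict[str, np.ndarray] = {}
    annot_rows = []
    for genotype in ("WT", "KIX"):
        for treatment in ("ctrl", "myb"):
            for rep in range(1, config.n_replicates + 1):
                sid = "%s_%s_r%d" % (genotype, treatment, rep)
                mean = baseline.copy()
                if treatment == "myb":
                    eff = effect.copy()
                    if genotype == "KIX":
                        eff[kix] = 0.0  # KIX-sensitive response abolished in mutant
                    mean = mean + eff
                noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
                cols[sid] = mean + noise
                annot_rows.append((sid, genotype, treatment, rep))

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(annot_rows, columns=["sample_id", "genotype", "treatment", "replicate"])
    samples = samples.set_index("sample_id")
    truth = pd.DataFrame({"status": status, "kix_sensitive": kix},
                         index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(values=values, samples=samples, truth=truth)
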