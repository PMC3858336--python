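"""Genetic-interaction (epistasis) estimation for four-genotype blood panels.

The design crosses a c-Myb heterozygous null allele with a CBP-KIX/p300-KIX
double heterozygote.  Under a multiplicative null, the phenotype of the
triple heterozygote (TH3) relative to wild type (WT0) equals the product of
the two intermediate genotypes' effects (CM1, CP2); on log-transformed
counts the interaction statistic is the linear contrast

    E = (WT0 + TH3) - (CM1 + CP2)

over the genotype log-means.  E = 0 means no epistasis; E > 0 is positive
epistasis (extreme genotype higher than the multiplicative expectation),
E < 0 negative.  Counts from independent experiments are adjusted for
machine drift by treating the experiment as a random intercept in a mixed
model (REML); the contrast's standard error comes from the covariance of
the fitted genotype means and the confidence interval uses a t quantile
with between-within degrees of freedom by default (a normal-quantile
interval is available).

Natural logarithms are used throughout.  Because E is a difference of log
differences, changing the log base rescales E and its CI by a constant but
leaves the sign and the z-statistic unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GENOTYPE_ROLES, BloodCountDataset

__all__ = [
    "EpistasisDesign",
    "GenotypeModelFit",
    "EpistasisEstimate",
    "log_transform",
    "fit_genotype_model",
    "estimate_epistasis",
    "anova_tukey",
    "run_epistasis_panel",
    "DEFAULT_DESIGN",
]

#: Contrast weights over (WT0, CM1, CP2, TH3).
CONTRAST = np.array([1.0, -1.0, -1.0, 1.0])

PANEL_COLUMNS = [
    "phenotype", "E_hat", "se", "ci_low", "ci_high", "level", "sign_class",
    "n_WT0", "n_CM1", "n_CP2", "n_TH3", "model_flavor",
]


@dataclass(frozen=True)
class EpistasisDesign:
    """Mapping from dataset genotype labels to the four analysis roles."""

    wt0: str = "WT0"
    cm1: str = "CM1"
    cp2: str = "CP2"
    th3: str = "TH3"

    def __post_init__(self) -> None:
        labels = [self.wt0, self.cm1, self.cp2, self.th3]
        if len(set(labels)) != 4:
            raise ValueError("design roles must map to four distinct labels, got %s" % labels)

    @property
    def role_to_label(self) -> dict[str, str]:
        return {"WT0": self.wt0, "CM1": self.cm1, "CP2": self.cp2, "TH3": self.th3}

    @property
    def label_to_role(self) -> dict[str, str]:
        return {v: k for k, v in self.role_to_label.items()}


DEFAULT_DESIGN = EpistasisDesign()


@dataclass
class GenotypeModelFit:
    """Fitted log-scale genotype means for one phenotype.

    ``means`` is ordered (WT0, CM1, CP2, TH3); ``cov`` is their 4x4
    covariance; ``sigma_b2``/``sigma_e2`` are the experiment and residual
    variance components; ``flavor`` is ``"mixed"`` or ``"fixed"``.
    """

    phenotype: str
    means: np.ndarray
    cov: np.ndarray
    sigma_b2: float
    sigma_e2: float
    flavor: str
    n_per_role: dict[str, int]
    n_experiments: int = 1
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.means.shape != (4,):
            raise ValueError("means must have four entries (WT0, CM1, CP2, TH3)")
        if self.cov.shape != (4, 4):
            raise ValueError("cov must be 4x4")
        if self.sigma_b2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class EpistasisEstimate:
    """The interaction estimate for one cell type: E, SE, CI and sign."""

    phenotype: str
    E_hat: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    sign_class: str
    n_per_role: dict[str, int] = field(default_factory=dict)
    model_flavor: str = "mixed"

    def to_dict(self) -> dict:
        d = {
            "phenotype": self.phenotype, "E_hat": self.E_hat, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "level": self.level,
            "sign_class": self.sign_class,
        }
        for role in GENOTYPE_ROLES:
            d["n_%s" % role] = self.n_per_role.get(role, 0)
        d["model_flavor"] = self.model_flavor
        return d


def log_transform(dataset: BloodCountDataset, phenotype: str,
                  offset: float = 0.0) -> pd.Series:
    """Natural log of one phenotype column, indexed by animal_id.

    Any value <= 0 (after the optional explicit ``offset``, default 0) is
    rejected with the offending animal named.
    """
    if phenotype not in dataset.frame.columns:
        raise KeyError("phenotype %r not in dataset" % (phenotype,))
    vals = pd.to_numeric(dataset.frame[phenotype], errors="raise") + offset
    bad = dataset.frame.loc[vals.to_numpy() <= 0, "animal_id"].tolist()
    if bad:
        raise ValueError(
            "non-positive %s value for animal(s) %s; pass a positive offset to shift"
            % (phenotype, bad[:5]))
    out = pd.Series(np.log(vals.to_numpy(dtype=float)),
                    index=dataset.frame["animal_id"], name=phenotype)
    out.attrs["log_base"] = "e"
    out.attrs["offset"] = offset
    return out


def _role_frame(dataset: BloodCountDataset, phenotype: str,
                design: EpistasisDesign, offset: float) -> pd.DataFrame:
    """Rows restricted to the four design genotypes, with role + log value."""
    l2r = design.label_to_role
    df = dataset.frame[dataset.frame["genotype"].isin(l2r)].copy()
    logs = log_transform(
        BloodCountDataset(frame=df, phenotypes=(phenotype,)), phenotype, offset=offset)
    df = df.assign(role=df["genotype"].map(l2r), logval=logs.to_numpy())
    counts = df["role"].value_counts()
    for role in GENOTYPE_ROLES:
        if counts.get(role, 0) < 2:
            raise ValueError(
                "role %s (label %r) has %d animal(s); need >= 2"
                % (role, design.role_to_label[role], counts.get(role, 0)))
    return df


def fit_genotype_model(dataset: BloodCountDataset, phenotype: str,
                       design: EpistasisDesign = DEFAULT_DESIGN,
                       batch_as_random: bool = True,
                       offset: float = 0.0) -> GenotypeModelFit:
    """REML mixed-model fit of log count ~ genotype + (1 | experiment).

    With a single experiment, or ``batch_as_random=False``, the fit reduces
    to fixed effects: per-genotype means with a pooled residual variance.
    A batch variance estimated at the boundary (0) is reported with a
    warning, not an error.
    """
    df = _role_frame(dataset, phenotype, design, offset)
    role_cat = pd.Categorical(df["role"], categories=list(GENOTYPE_ROLES))
    n_per_role = {r: int((df["role"] == r).sum()) for r in GENOTYPE_ROLES}
    n_exp = df["experiment_id"].nunique()

    if batch_as_random and n_exp >= 2:
        import statsmodels.api as sm

        exog = pd.get_dummies(role_cat, dtype=float).to_numpy()  # cell-means coding
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["logval"].to_numpy(), exog,
                               groups=df["experiment_id"].to_numpy())
            res = model.fit(reml=True)
        means = np.asarray(res.fe_params, dtype=float)
        cov = np.asarray(res.cov_params())[:4, :4]
        sigma_e2 = float(res.scale)
        sigma_b2 = float(np.asarray(res.cov_re)[0, 0])
        if sigma_b2 <= 1e-12:
            warnings.warn(
                "experiment variance estimated at the boundary (0); fit is "
                "equivalent to fixed effects", RuntimeWarning, stacklevel=2)
            sigma_b2 = 0.0
        flavor = "mixed"
    else:
        grp = df.groupby("role", observed=True)["logval"]
        means = np.array([grp.mean()[r] for r in GENOTYPE_ROLES])
        resid = df["logval"].to_numpy() - df["role"].map(grp.mean()).to_numpy()
        dof = len(df) - 4
        sigma_e2 = float(np.sum(resid ** 2) / dof) if dof > 0 else 0.0
        cov = np.diag([sigma_e2 / n_per_role[r] for r in GENOTYPE_ROLES])
        sigma_b2 = 0.0
        flavor = "fixed"

    return GenotypeModelFit(phenotype=phenotype, means=means, cov=cov,
                            sigma_b2=sigma_b2, sigma_e2=sigma_e2, flavor=flavor,
                            n_per_role=n_per_role, n_experiments=n_exp)


def _sign_class(ci_low: float, ci_high: float) -> str:
    if ci_low > 0:
        return "positive"
    if ci_high < 0:
        return "negative"
    return "none"


def estimate_epistasis(fit: GenotypeModelFit, level: float = 0.95,
                       interval: str = "t") -> EpistasisEstimate:
    """E = (WT0 + TH3) - (CM1 + CP2) with its SE, CI and sign class.

    SE = sqrt(c' V c) with c = (+1, -1, -1, +1) over the fitted genotype
    means.  ``interval="t"`` (default) uses a t quantile with between-within
    residual degrees of freedom N - 4 - (n_experiments - 1), which is
    calibrated at small study sizes; ``interval="z"`` uses the normal
    quantile (slightly anti-conservative).  Zero-variance data yield SE = 0
    and a degenerate CI equal to the point estimate.  The sign class is
    ``positive`` iff ci_low > 0, ``negative`` iff ci_high < 0, else ``none``.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1), got %r" % (level,))
    e_hat = float(CONTRAST @ fit.means)
    var = float(CONTRAST @ fit.cov @ CONTRAST)
    se = float(np.sqrt(max(var, 0.0)))
    if interval == "z":
        crit = float(stats.norm.ppf(0.5 + level / 2))
    elif interval == "t":
        n_total = sum(fit.n_per_role.values())
        df_resid = max(n_total - 4 - max(fit.n_experiments - 1, 0), 1)
        crit = float(stats.t.ppf(0.5 + level / 2, df_resid))
    else:
        raise ValueError("interval must be 'z' or 't', got %r" % (interval,))
    lo, hi = e_hat - crit * se, e_hat + crit * se
    return EpistasisEstimate(
        phenotype=fit.phenotype, E_hat=e_hat, se=se, ci_low=lo, ci_high=hi,
        level=level, sign_class=_sign_class(lo, hi),
        n_per_role=dict(fit.n_per_role), model_flavor=fit.flavor)


def anova_tukey(dataset: BloodCountDataset, phenotype: str,
                genotypes: list[str] | None = None,
                log: bool = True, alpha: float = 0.05):
    """One-way ANOVA across genotypes with Tukey HSD pairwise post tests.

    Returns ``(F, p, table)`` where ``table`` has one row per genotype pair
    with the mean difference, Tukey-adjusted p and a star code
    (* p<0.05, ** p<0.01, *** p<0.001).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = dataset.frame
    if genotypes is not None:
        df = df[df["genotype"].isin(genotypes)]
    groups = {g: sub[phenotype].to_numpy(dtype=float) for g, sub in df.groupby("genotype")}
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError("group(s) with < 2 observations: %s" % small)
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype groups, got %d" % len(groups))
    if log:
        for g, v in groups.items():
            if (v <= 0).any():
                raise ValueError("non-positive %s values in group %s" % (phenotype, g))
        groups = {g: np.log(v) for g, v in groups.items()}

    names = sorted(groups)
    f_stat, p_overall = stats.f_oneway(*[groups[g] for g in names])
    values = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    table = table.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    table["p_adj"] = tk.pvalues  # full precision, not the rounded summary
    table["stars"] = pd.cut(table["p_adj"], [-np.inf, 0.001, 0.01, 0.05, np.inf],
                            labels=["***", "**", "*", "ns"]).astype(str)
    keep = ["group1", "group2", "mean_diff", "p_adj", "stars"]
    return float(f_stat), float(p_overall), table[keep]


def run_epistasis_panel(dataset: BloodCountDataset,
                        design: EpistasisDesign = DEFAULT_DESIGN,
                        phenotypes: list[str] | None = None,
                        level: float = 0.95,
                        batch_as_random: bool = True,
                        interval: str = "t") -> pd.DataFrame:
    """One epistasis estimate per cell type, no multiplicity adjustment.

    Each phenotype is estimated independently at the requested confidence
    level; p-values/CIs are deliberately NOT adjusted for the number of cell
    types.  A phenotype whose fit fails is reported via a warning and
    skipped; the remaining rows are returned in the requested order.
    """
    if phenotypes is None:
        phenotypes = list(dataset.phenotypes)
    rows = []
    for p in phenotypes:
        try:
            fit = fit_genotype_model(dataset, p, design=design,
                                     batch_as_random=batch_as_random)
            est = estimate_epistasis(fit, level=level, interval=interval)
        except (ValueError, KeyError) as exc:
            warnings.warn("phenotype %r skipped: %s" % (p, exc), RuntimeWarning,
                          stacklevel=2)
            continue
        rows.append(est.to_dict())
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)
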