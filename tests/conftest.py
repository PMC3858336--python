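"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pandas as pd
import pytest

from epistatrio import (BloodSimConfig, ExpressionMatrix, ExprSimConfig,
                        simulate_blood_counts, simulate_expression)


@pytest.fixture(scope="session")
def blood_dataset():
    """A mid-sized balanced four-genotype dataset with positive interaction."""
    cfg = BloodSimConfig(n_per_group=15, n_experiments=5, batch_sd=0.1,
                         residual_sd=0.2, true_E=0.41, seed=42)
    return simulate_blood_counts(cfg)


@pytest.fixture(scope="session")
def expr_matrix():
    """A planted expression matrix with activated/repressed/KIX-sensitive genes."""
    cfg = ExprSimConfig(n_genes=2000, n_replicates=2, noise_sd=0.0,
                        frac_kix_sensitive=0.5, seed=7)
    return simulate_expression(cfg)


def random_expression(rng, n_genes=100, n_per_class=5, loc=7.0, scale=1.0):
    """A null genes x (A,B) matrix for enrichment tests."""
    vals = rng.normal(loc, scale, size=(n_genes, 2 * n_per_class))
    sample_ids = ["s%02d" % i for i in range(2 * n_per_class)]
    samples = pd.DataFrame(
        {"genotype": ["A"] * n_per_class + ["B"] * n_per_class,
         "treatment": "na", "replicate": 1}, index=sample_ids)
    genes = ["g%04d" % i for i in range(n_genes)]
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=sample_ids),
        samples=samples)


def es_bruteforce(ids_ranked, metric_ranked, members, p_w):
    """Plain-loop running-sum oracle, independent of the vectorized path."""
    members = set(members)
    hits = [i for i, g in enumerate(ids_ranked) if g in members]
    n = len(ids_ranked)
    n_hit = len(hits)
    assert 0 < n_hit < n
    norm = sum(abs(metric_ranked[i]) ** p_w for i in hits)
    cur, best = 0.0, 0.0
    walk = []
    for i, g in enumerate(ids_ranked):
        if g in members:
            cur += (abs(metric_ranked[i]) ** p_w / norm) if norm > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        walk.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best, walk


def plain_log_contrast(dataset, phenotype):
    """Group-log-mean contrast (WT0 + TH3) - (CM1 + CP2), no model."""
    df = dataset.frame
    g = df.assign(l=np.log(df[phenotype].to_numpy(dtype=float))).groupby("genotype")["l"].mean()
    return float(g["WT0"] + g["TH3"] - g["CM1"] - g["CP2"])


def noiseless_dataset(values_by_role, n=4):
    """Four genotype groups with every animal identical within a group."""
    rows = []
    i = 0
    for role, v in values_by_role.items():
        for _ in range(n):
            i += 1
            rows.append({"animal_id": "A%03d" % i, "genotype": role,
                         "experiment_id": "E01", "strain": "s",
                         "age_months": 1.5, "count": v})
    from epistatrio import BloodCountDataset
    return BloodCountDataset(frame=pd.DataFrame(rows), phenotypes=("count",))
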