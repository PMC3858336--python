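"""Readers and writers for the pipeline's text formats.

Blood-count tables are UTF-8 comma-separated CSV with a fixed header;
expression matrices travel as GCT 1.2 plus a tab-separated sample-annotation
file; sample classes as CLS; gene sets as GMT; design mappings and stage
parameters as YAML.  All readers validate rather than coerce: a malformed
numeric field or a dimension mismatch is an error naming the offender.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epistasis import EpistasisDesign
from .synthetic import ID_COLUMNS, BloodCountDataset, ExpressionMatrix

__all__ = [
    "read_counts_csv", "write_counts_csv",
    "read_gct", "write_gct",
    "read_cls", "write_cls",
    "read_gmt", "write_gmt",
    "read_sample_annotations", "write_sample_annotations",
    "read_design_yaml",
    "read_expression", "write_expression",
]


# ---------------------------------------------------------------------------
# Blood counts (CSV)
# ---------------------------------------------------------------------------

def read_counts_csv(path) -> BloodCountDataset:
    """Read a per-animal blood-count table.

    Requires the header columns ``animal_id``, ``genotype``,
    ``experiment_id`` and at least one phenotype column; ``strain`` and
    ``age_months`` are optional.  Duplicate animal ids and non-numeric
    phenotype values are rejected with row numbers.
    """
    df = pd.read_csv(path, dtype=str)
    required = ("animal_id", "genotype", "experiment_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError("%s: missing required column(s): %s" % (path, ", ".join(missing)))
    phenotypes = [c for c in df.columns if c not in ID_COLUMNS]
    if not phenotypes:
        raise ValueError("%s: no phenotype columns found" % (path,))
    if df["animal_id"].duplicated().any():
        rows = (df.index[df["animal_id"].duplicated()] + 2).tolist()
        raise ValueError("%s: duplicate animal_id at row(s) %s" % (path, rows[:5]))
    for p in phenotypes:
        vals = pd.to_numeric(df[p], errors="coerce")
        if vals.isna().any():
            rows = (df.index[vals.isna()] + 2).tolist()
            raise ValueError("%s: non-numeric %s value at row(s) %s" % (path, p, rows[:5]))
        df[p] = vals.astype(float)
    if "age_months" in df.columns:
        df["age_months"] = pd.to_numeric(df["age_months"], errors="coerce")
    return BloodCountDataset(frame=df, phenotypes=tuple(phenotypes))


def write_counts_csv(dataset: BloodCountDataset, path) -> None:
    cols = [c for c in ID_COLUMNS if c in dataset.frame.columns] + list(dataset.phenotypes)
    dataset.frame[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GCT 1.2 (expression matrix)
# ---------------------------------------------------------------------------

def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix into a genes x samples DataFrame.

    The declared dimensions are validated against the body; the Description
    column is dropped.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError("%s: expected GCT version line '#1.2', got %r" % (path, version))
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError("%s: malformed GCT dimension line" % (path,))
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if len(body) != n_genes:
        raise ValueError("%s: GCT declares %d rows but body has %d" % (path, n_genes, len(body)))
    sample_cols = [c for c in body.columns if c not in ("Name", "NAME", "Description")]
    if len(sample_cols) != n_samples:
        raise ValueError("%s: GCT declares %d samples but body has %d"
                         % (path, n_samples, len(sample_cols)))
    name_col = "Name" if "Name" in body.columns else "NAME"
    out = body.set_index(name_col)[sample_cols].astype(float)
    out.index.name = "gene_id"
    return out


def write_gct(values: pd.DataFrame, path, descriptions=None) -> None:
    """Write a genes x samples DataFrame as GCT 1.2."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write("%d\t%d\n" % values.shape)
        body = values.copy()
        body.insert(0, "Description", descriptions if descriptions is not None else "na")
        body.index.name = "Name"
        body.to_csv(fh, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# CLS (sample classes)
# ---------------------------------------------------------------------------

def read_cls(path) -> tuple[list[str], list[str]]:
    """Read a categorical CLS file -> (per-sample labels, class names)."""
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    if len(lines) < 3:
        raise ValueError("%s: CLS file needs three lines" % (path,))
    head = lines[0].split()
    n_samples, n_classes = int(head[0]), int(head[1])
    if not lines[1].startswith("#"):
        raise ValueError("%s: CLS second line must start with '#'" % (path,))
    class_names = lines[1].lstrip("#").split()
    if len(class_names) != n_classes:
        raise ValueError("%s: CLS declares %d classes but names %d"
                         % (path, n_classes, len(class_names)))
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ValueError("%s: CLS declares %d samples but labels %d"
                         % (path, n_samples, len(tokens)))
    labels = []
    for t in tokens:
        if t in class_names:
            labels.append(t)
        elif t.isdigit() and int(t) < n_classes:
            labels.append(class_names[int(t)])
        else:
            raise ValueError("%s: unknown class label %r" % (path, t))
    return labels, class_names


def write_cls(labels: list[str], path) -> None:
    names = list(dict.fromkeys(labels))  # first-appearance order
    with open(path, "w") as fh:
        fh.write("%d %d 1\n" % (len(labels), len(names)))
        fh.write("# %s\n" % " ".join(names))
        fh.write("%s\n" % " ".join(str(names.index(l)) for l in labels))


# ---------------------------------------------------------------------------
# GMT (gene sets)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file -> {set name: member ids}; duplicates deduplicated
    with a warning, empty sets rejected."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(open(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError("%s: line %d has no members (GMT needs name, "
                             "description, >=1 gene)" % (path, i))
        name, members = fields[0], [g for g in fields[2:] if g]
        if not members:
            raise ValueError("%s: line %d (%r) has an empty member list" % (path, i, name))
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            warnings.warn("%s: set %r has duplicate members; deduplicated"
                          % (path, name), RuntimeWarning, stacklevel=2)
        if name in sets:
            warnings.warn("%s: duplicate set name %r; keeping the first"
                          % (path, name), RuntimeWarning, stacklevel=2)
            continue
        sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# Sample annotations (TSV) and YAML configs
# ---------------------------------------------------------------------------

def read_sample_annotations(path) -> pd.DataFrame:
    """TSV with columns sample_id, genotype, treatment, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sample_id", "genotype", "treatment")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError("%s: missing annotation column(s): %s" % (path, ", ".join(missing)))
    if df["sample_id"].duplicated().any():
        raise ValueError("%s: duplicate sample_id" % (path,))
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    return df.set_index("sample_id")


def write_sample_annotations(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_design_yaml(path) -> EpistasisDesign:
    """YAML mapping role -> genotype label, e.g. ``wt0: WT``."""
    raw = yaml.safe_load(open(path))
    if not isinstance(raw, dict):
        raise ValueError("%s: design file must be a mapping of role -> label" % (path,))
    lower = {str(k).lower(): str(v) for k, v in raw.items()}
    missing = [r for r in ("wt0", "cm1", "cp2", "th3") if r not in lower]
    if missing:
        raise ValueError("%s: design missing role(s): %s" % (path, ", ".join(missing)))
    return EpistasisDesign(wt0=lower["wt0"], cm1=lower["cm1"],
                           cp2=lower["cp2"], th3=lower["th3"])


def read_expression(gct_path, annot_path, truth_path=None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from a GCT + annotation TSV (+ truth)."""
    values = read_gct(gct_path)
    samples = read_sample_annotations(annot_path)
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        # keep_default_na: the status label "null" is data, not missingness
        truth = pd.read_csv(truth_path, sep="\t", index_col=0,
                            keep_default_na=False)
        if "kix_sensitive" in truth.columns:
            truth["kix_sensitive"] = truth["kix_sensitive"].map(
                {"True": True, "False": False, True: True, False: False})
    return ExpressionMatrix(values=values, samples=samples, truth=truth)


def write_expression(matrix: ExpressionMatrix, out_dir, stem: str = "expr") -> dict[str, Path]:
    """Write GCT + annotations (+ truth sidecar); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"gct": out_dir / ("%s.gct" % stem),
             "annot": out_dir / ("%s_samples.tsv" % stem)}
    write_gct(matrix.values, paths["gct"])
    write_sample_annotations(matrix.samples, paths["annot"])
    if matrix.truth is not None:
        paths["truth"] = out_dir / ("%s_truth.tsv" % stem)
        matrix.truth.to_csv(paths["truth"], sep="\t")
    return paths
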