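"""Readers and writers for the pipeline's plain-text dialects.

Counts: tab-separated, first column ``gene_id``, one column per library.
Sample sheet: CSV with columns sample_id, fraction, condition, replicate.
Truth: TSV with gene_id, class, gamma2, gamma3.  Cohort: CSV with gene_id,
group, value.  Survival: CSV with patient_id, time, event, expression.
Configs round-trip through YAML, run summaries through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignError, validate_counts, validate_samples


def read_counts(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    if counts.columns[0] != "gene_id":
        raise DesignError(
            f"counts file {path}: first column must be 'gene_id', "
            f"got {counts.columns[0]!r}"
        )
    return counts.set_index("gene_id")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path))


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "fraction", "condition", "replicate"]
    samples[cols].to_csv(path, index=False)


def load_validated(counts_path: str | Path, samples_path: str | Path):
    """Read and cross-validate counts and sample sheet."""
    samples = read_sample_sheet(samples_path)
    counts = validate_counts(read_counts(counts_path), samples)
    return counts, samples


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_survival(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["event"] = table["event"].astype(bool)
    return table


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
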