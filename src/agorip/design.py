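"""Experimental design of an Ago-RIP-Seq run and input validation.

The design is a full factorial of three sequencing fractions (``ago`` —
Argonaute immunoprecipitate, ``igg`` — nonspecific-antibody background IP,
``input`` — total lysate) by two transfection conditions (``mir`` — miRNA
mimic, ``ctrl`` — negative-control mimic), with ``R`` biological replicates:
6·R libraries in total.

Counts are carried as a :class:`pandas.DataFrame` (genes × libraries,
non-negative integers); the sample sheet as a DataFrame with columns
``sample_id, fraction, condition, replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRACTIONS = ("ago", "igg", "input")
CONDITIONS = ("mir", "ctrl")

#: Fixed coefficient order of the six design cells used throughout the
#: package (model coefficients, contrast weights, simulator means).
CELL_ORDER = (
    "input_ctrl",
    "input_mir",
    "igg_ctrl",
    "igg_mir",
    "ago_ctrl",
    "ago_mir",
)

SAMPLE_SHEET_COLUMNS = ("sample_id", "fraction", "condition", "replicate")


class DesignError(ValueError):
    """Raised when counts or sample sheet violate the design contract."""


@dataclass(frozen=True)
class SampleDescriptor:
    """One sequencing library: its fraction, condition and replicate."""

    sample_id: str
    fraction: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise DesignError(
                f"sample {self.sample_id!r}: fraction {self.fraction!r} "
                f"not one of {FRACTIONS}"
            )
        if self.condition not in CONDITIONS:
            raise DesignError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"not one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise DesignError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )

    @property
    def cell(self) -> str:
        return f"{self.fraction}_{self.condition}"


def cell_label(fraction: str, condition: str) -> str:
    """Return the design-cell label, e.g. ``("ago", "mir") -> "ago_mir"``."""
    return f"{fraction}_{condition}"


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it with a ``cell`` column added.

    Checks column presence, enum values, and uniqueness of sample ids and
    of (fraction, condition, replicate) triples.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise DesignError(f"sample sheet missing columns: {missing}")
    samples = samples.copy()
    for desc_cols, allowed in (("fraction", FRACTIONS), ("condition", CONDITIONS)):
        bad = samples.loc[~samples[desc_cols].isin(allowed), "sample_id"]
        if len(bad):
            raise DesignError(
                f"invalid {desc_cols} value(s) for sample(s) {list(bad)}; "
                f"allowed: {allowed}"
            )
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        raise DesignError(f"duplicate sample_id(s): {sorted(set(dup))}")
    samples["replicate"] = samples["replicate"].astype(int)
    if (samples["replicate"] < 1).any():
        raise DesignError("replicate indices must be positive integers")
    triple = samples[["fraction", "condition", "replicate"]]
    if triple.duplicated().any():
        dup_rows = samples[triple.duplicated(keep=False)]
        raise DesignError(
            "duplicate (fraction, condition, replicate) triples:\n"
            f"{dup_rows.to_string(index=False)}"
        )
    samples["cell"] = samples["fraction"] + "_" + samples["condition"]
    return samples


def validate_counts(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene × library count matrix against a sample sheet.

    Requires unique gene ids, non-negative integer counts, and a column
    for every sample (columns are reordered to sample-sheet order).
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise DesignError("count matrix is empty")
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()]
        raise DesignError(f"duplicate gene identifier(s): {sorted(set(dup))}")
    missing = [s for s in samples["sample_id"] if s not in counts.columns]
    if missing:
        raise DesignError(f"count matrix lacks column(s) for sample(s): {missing}")
    counts = counts[list(samples["sample_id"])]
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DesignError("count matrix contains non-numeric entries")
    if (values < 0).any():
        genes = counts.index[(values < 0).any(axis=1)]
        raise DesignError(f"negative counts for gene(s): {list(genes[:10])}")
    if not np.allclose(values, np.round(values)):
        raise DesignError("count matrix contains non-integer entries")
    return counts.astype(np.int64)


def require_complete_design(samples: pd.DataFrame) -> None:
    """Check that all six fraction × condition cells are present (pooled)."""
    present = set(samples["fraction"] + "_" + samples["condition"])
    absent = [c for c in CELL_ORDER if c not in present]
    if absent:
        raise DesignError(f"design is missing fraction×condition cell(s): {absent}")


def replicate_completeness(samples: pd.DataFrame) -> pd.DataFrame:
    """Boolean table replicate × cell: which design cells each replicate has."""
    table = (
        samples.assign(present=True)
        .pivot_table(index="replicate", columns="cell", values="present", aggfunc="any")
        .reindex(columns=list(CELL_ORDER))
        .isin([True])  # NaN (absent cell) -> False without dtype games
    )
    return table
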