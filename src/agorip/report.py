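"""Human-readable report over a completed run directory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .io import read_json

REQUIRED_FILES = ("contrasts.tsv", "calls.tsv", "cascade.tsv", "summary.json")


class ReportError(FileNotFoundError):
    """A run directory is missing expected output files."""


def render_report(run_dir: str | Path) -> Path:
    """Render cascade table, contrast histograms and QC notes.

    Writes ``report.txt`` and one histogram PNG per contrast into the run
    directory; deterministic given the run outputs.  Raises
    :class:`ReportError` listing every missing expected file.
    """
    run_dir = Path(run_dir)
    missing = [f for f in REQUIRED_FILES if not (run_dir / f).exists()]
    if missing:
        raise ReportError(
            f"run directory {run_dir} is missing expected file(s): {missing}"
        )
    contrasts = pd.read_csv(run_dir / "contrasts.tsv", sep="\t")
    cascade = pd.read_csv(run_dir / "cascade.tsv", sep="\t")
    summary = read_json(run_dir / "summary.json")

    lines = [
        "agorip run report",
        "=================",
        "",
        f"genes: {summary['n_genes']}   libraries: {summary['n_libraries']}",
        f"non-converged fits: {summary['n_not_converged']}   "
        f"zero-cell adjusted genes: {summary['n_zero_cell_adjusted']}",
        "",
        "filter cascade",
        "--------------",
        cascade.to_string(index=False),
        "",
        "contrast estimate summary (log2FC)",
        "----------------------------------",
    ]
    for name in ("C1", "C2", "C3"):
        col = f"{name}_estimate"
        stats = contrasts[col].describe()
        lines.append(
            f"{name}: mean {stats['mean']:+.3f}  sd {stats['std']:.3f}  "
            f"median {stats['50%']:+.3f}"
        )
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(contrasts[col].dropna(), bins=60, color="#46689b")
        ax.set_xlabel(f"{name} estimate (log2FC)")
        ax.set_ylabel("genes")
        fig.tight_layout()
        fig.savefig(run_dir / f"hist_{name}.png", dpi=120)
        plt.close(fig)
    if "recovery" in summary:
        r = summary["recovery"]
        lines += [
            "",
            "recovery against planted truth",
            "------------------------------",
            f"tier {r['tier']}: sensitivity {r['sensitivity']:.3f}  "
            f"FDR {r['fdr']:.3f}  called {r['n_called']}",
        ]
    # calibration diagnostic: p-value distribution of C2 should be flat-ish
    # under the null majority
    p = contrasts["C2_p"].dropna()
    frac = float((p < 0.05).mean()) if len(p) else float("nan")
    lines += ["", f"fraction of genes with C2 p < 0.05: {frac:.4f}", ""]
    out = run_dir / "report.txt"
    out.write_text("\n".join(lines))
    return out
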