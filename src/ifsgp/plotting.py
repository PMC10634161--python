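"""Accuracy-curve plots mirroring the standard presentation of an IFS run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import EvaluationReport


def plot_report(report: EvaluationReport, path: str | Path, title: str | None = None) -> None:
    """Accuracy vs log SNP count with the smoothed trend, the optimum and
    the full-model baseline with its +/- SE band."""
    curve = report.curve
    smoothed = report.selection.smoothed

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(curve.snp_counts, curve.mean_r2, ".", color="0.6", ms=4, label="mean accuracy")
    ax.plot(smoothed.snp_counts, smoothed.smoothed_r2, "k-", lw=1.5, label="smoothed trend")

    baseline = curve.mean_r2[-1]
    band = curve.se_r2[-1]
    ax.axhline(baseline, color="k", lw=1)
    ax.axhspan(baseline - band, baseline + band, color="0.85", zorder=0)
    ax.axvline(report.selection.optimal_count, color="green", lw=1.5, label="optimum")

    ax.set_xscale("log")
    ax.set_xlabel("number of SNPs")
    ax.set_ylabel("prediction accuracy (R$^2$)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
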