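"""Run outputs: tab-delimited result files, matched-read FASTA, plots.

Three text outputs are produced per run: one ``<file>_results.txt`` per
input file (selected total, per-probe counts/percentages and per-read
hit lines), one aggregated ``total_results.txt`` (one row per
file x probe), and one timestamped ``summary_result_<YYYYMMDD_HHMMSS>.txt``.
Matched reads are additionally exported per file as FASTA for
downstream validation (alignment, locus verification, phylogenetics).
Plots are views over ``total_results.txt``, never independent sources:
a probes-by-files percentage heatmap plus per-file and per-probe bar
charts, all written as 300-dpi PNG through the file backend.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; plots are always file-backed

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .engine import RunSummary

__all__ = [
    "total_results_frame",
    "write_outputs",
    "build_matrix",
    "render_plots",
]

_DPI = 300
_PCT_FMT = "{:.4f}"  # sub-0.01% detections are real; four decimals keep them


def total_results_frame(run: RunSummary) -> pd.DataFrame:
    """Tidy per-(file, probe) table backing ``total_results.txt``."""
    rows = []
    for fs in run.files:
        for probe in run.probe_names:
            rows.append({
                "file": fs.file,
                "probe": probe,
                "matched": fs.counts[probe],
                "total": fs.total_selected,
                "percent": fs.percentage(probe),
            })
    return pd.DataFrame(rows, columns=["file", "probe", "matched", "total", "percent"])


def write_outputs(run: RunSummary, out_dir: str | Path,
                  timestamp: datetime | None = None) -> dict[str, Path]:
    """Write all text outputs; returns a name -> path map.

    ``timestamp`` is injectable so reruns can be byte-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_test"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    ts = (timestamp or datetime.now()).strftime("%Y%m%d_%H%M%S")

    # Per-file results + matched-read FASTA.
    for fs in run.files:
        stem = _strip_seq_suffix(fs.file)
        res_path = out_dir / f"{stem}_results.txt"
        with open(res_path, "w") as fh:
            fh.write(f"file\t{fs.file}\n")
            fh.write(f"total_selected\t{fs.total_selected}\n")
            if fs.error:
                fh.write(f"error\t{fs.error}\n")
            fh.write("probe\tmatched\tpercent\texcluded_short\n")
            for probe_name in run.probe_names:
                fh.write(
                    f"{probe_name}\t{fs.counts[probe_name]}\t"
                    f"{_PCT_FMT.format(fs.percentage(probe_name))}\t"
                    f"{fs.excluded[probe_name]}\n"
                )
            fh.write("read_id\tprobe\tscore\tstrand\n")
            for m in fs.matches:
                fh.write(f"{m.read_id}\t{m.probe_name}\t{m.score:.4f}\t{m.strand}\n")
        written[res_path.name] = res_path

        fasta_path = out_dir / f"{stem}_matched_reads.fasta"
        with open(fasta_path, "w") as fh:
            # One entry per (read, probe) hit: a read matched by two
            # probes appears twice, under distinct headers.
            for m in fs.matches:
                fh.write(f">{m.read_id}|{m.probe_name}|{m.score:.4f}|{m.strand}\n")
                fh.write(f"{m.sequence}\n")
        written[fasta_path.name] = fasta_path

    # Aggregated table.
    frame = total_results_frame(run)
    total_path = out_dir / "total_results.txt"
    frame.to_csv(total_path, sep="\t", index=False, float_format="%.4f")
    written["total_results.txt"] = total_path

    # Timestamped run summary.
    summary_path = out_dir / f"summary_result_{ts}.txt"
    with open(summary_path, "w") as fh:
        fh.write(f"threshold\t{run.config.match.threshold}\n")
        fh.write(f"extract_ratio\t{run.config.extract_ratio}\n")
        fh.write(f"batch_size\t{run.config.batch_size}\n")
        fh.write(f"seed\t{run.config.seed}\n")
        fh.write(f"elapsed_seconds\t{run.elapsed:.2f}\n")
        fh.write("file\ttotal_selected\ttotal_matched\tstatus\n")
        for fs in run.files:
            status = fs.error or "ok"
            fh.write(f"{fs.file}\t{fs.total_selected}\t"
                     f"{sum(fs.counts.values())}\t{status}\n")
    written[summary_path.name] = summary_path
    return written


def _strip_seq_suffix(name: str) -> str:
    stem = name.removesuffix(".gz")
    for ext in (".fastq", ".fq", ".fasta", ".fa", ".fna"):
        if stem.endswith(ext):
            return stem[: -len(ext)]
    return stem


def build_matrix(run: RunSummary) -> pd.DataFrame:
    """Probes-by-files percentage matrix (heatmap source), via pivot."""
    frame = total_results_frame(run)
    matrix = frame.pivot(index="probe", columns="file", values="percent")
    # Restore panel / input order lost by pivot's lexicographic sort.
    return matrix.reindex(index=run.probe_names,
                          columns=[fs.file for fs in run.files])


def render_plots(run: RunSummary, matrix: pd.DataFrame,
                 out_dir: str | Path) -> list[Path]:
    """Render the heatmap and the per-file / per-probe bar charts."""
    out_dir = Path(out_dir)
    files_dir = out_dir / "input_files"
    probes_dir = out_dir / "probes"
    files_dir.mkdir(parents=True, exist_ok=True)
    probes_dir.mkdir(parents=True, exist_ok=True)
    images: list[Path] = []

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * len(matrix.columns) + 2),
                 max(3.0, 0.25 * len(matrix.index) + 1.5)))
    sns.heatmap(matrix, cmap="coolwarm", ax=ax,
                cbar_kws={"label": "matched reads (%)"})
    ax.set_xlabel("file")
    ax.set_ylabel("probe")
    fig.tight_layout()
    heatmap_path = out_dir / "Total_heatmap.png"
    fig.savefig(heatmap_path, dpi=_DPI)
    plt.close(fig)
    images.append(heatmap_path)

    for fs in run.files:
        fig, ax = plt.subplots(figsize=(max(4.0, 0.3 * len(run.probe_names) + 1), 3.5))
        ax.bar(run.probe_names, [fs.counts[p] for p in run.probe_names])
        ax.set_ylabel("matched reads")
        ax.set_title(fs.file)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        path = files_dir / f"{_strip_seq_suffix(fs.file)}.png"
        fig.savefig(path, dpi=_DPI)
        plt.close(fig)
        images.append(path)

    file_names = [fs.file for fs in run.files]
    for probe_name in run.probe_names:
        fig, ax = plt.subplots(figsize=(max(4.0, 0.3 * len(file_names) + 1), 3.5))
        ax.bar(file_names, [fs.counts[probe_name] for fs in run.files])
        ax.set_ylabel("matched reads")
        ax.set_title(probe_name)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        path = probes_dir / f"{_safe_name(probe_name)}.png"
        fig.savefig(path, dpi=_DPI)
        plt.close(fig)
        images.append(path)
    return images


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)
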