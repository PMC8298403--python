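"""Descriptive outputs: bubble-plot statistics, similarity/dissimilarity
summaries, and confusion-matrix renderings.

Figures are views: every rendered figure is backed by a machine-readable
sidecar CSV written alongside it, and the figure is generated from exactly
those numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .io import FeatureMatrix
from .similarity import (
    DISSIMILARITY_THRESHOLD,
    DissimilarityMatrix,
    SimilarityReport,
    rms_patterns,
    similarity_table,
)

logger = logging.getLogger(__name__)


@dataclass
class BubblePlotData:
    """Per (participant, movement): channel means/SDs of normalized RMS
    across the 15 observations, plus the repetition-averaged envelope."""

    participant_id: int
    movement_code: str
    channel_mean: np.ndarray  # (8,)
    channel_sd: np.ndarray  # (8,)
    mean_envelope: np.ndarray | None = None  # (8, n) averaged smoothed trace


def bubble_data(
    fm: FeatureMatrix, envelopes: dict[tuple[int, str], np.ndarray] | None = None
) -> list[BubblePlotData]:
    """Channel-wise mean and SD of the block-normalized RMS patterns.

    ``envelopes`` optionally maps (participant, movement) to a stack of
    per-repetition rectified-smoothed traces (n_reps x 8 x n); their
    pointwise mean becomes the plotted signal trace.
    """
    patterns = rms_patterns(fm)
    by_block: dict[tuple[int, str], list[np.ndarray]] = {}
    for p in patterns:
        by_block.setdefault((p.participant_id, p.movement_code), []).append(p.values)
    out = []
    for (pid, code), vals in sorted(by_block.items()):
        arr = np.vstack(vals)
        env = None
        if envelopes and (pid, code) in envelopes:
            env = np.mean(envelopes[(pid, code)], axis=0)
        out.append(BubblePlotData(pid, code, arr.mean(axis=0), arr.std(axis=0), env))
    return out


def _write_sidecar(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def render_reports(
    out_dir: str | Path,
    feature_matrix: FeatureMatrix | None = None,
    similarity_reports: list[SimilarityReport] | None = None,
    dissimilarities: list[DissimilarityMatrix] | None = None,
    classifications: dict[str, ClassificationReport] | None = None,
    fmt: str = "png",
    similarity_ylim: tuple[float, float] = (0.3, 1.0),
) -> list[Path]:
    """Render every figure whose inputs are present; returns written paths.

    Raises ``ValueError`` when no stage output at all is supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if not any([feature_matrix, similarity_reports, dissimilarities, classifications]):
        raise ValueError("no stage outputs supplied: nothing to render")

    if feature_matrix is not None and len(feature_matrix):
        for bd in bubble_data(feature_matrix):
            stem = f"bubble_p{bd.participant_id:02d}_{bd.movement_code}"
            side = pd.DataFrame(
                {
                    "channel": np.arange(1, 9),
                    "mean_norm_rms": bd.channel_mean,
                    "sd_norm_rms": bd.channel_sd,
                }
            )
            _write_sidecar(side, out_dir / f"{stem}.csv")
            fig, ax = plt.subplots(figsize=(5, 3))
            ax.scatter(
                np.arange(1, 9),
                bd.channel_mean,
                s=200 + 4000 * bd.channel_sd,
                alpha=0.5,
            )
            ax.set(xlabel="channel", ylabel="mean normalized RMS",
                   title=f"P{bd.participant_id} {bd.movement_code}", ylim=(0, 1.05))
            fig.savefig(out_dir / f"{stem}.{fmt}", dpi=100)
            plt.close(fig)
            written += [out_dir / f"{stem}.csv", out_dir / f"{stem}.{fmt}"]

    if similarity_reports:
        table = similarity_table(similarity_reports)
        _write_sidecar(table, out_dir / "similarity.csv")
        fig, ax = plt.subplots(figsize=(8, 3))
        for code, grp in table.groupby("movement_code"):
            ax.bar(
                grp["participant_id"] + 0.1 * int(str(code)[1:]),
                grp["similarity"],
                width=0.1,
                label=str(code),
            )
        ax.set(xlabel="participant", ylabel="similarity", ylim=similarity_ylim)
        ax.legend(fontsize=6, ncols=6)
        fig.savefig(out_dir / f"similarity.{fmt}", dpi=100)
        plt.close(fig)
        written += [out_dir / "similarity.csv", out_dir / f"similarity.{fmt}"]

    if dissimilarities:
        for dm in dissimilarities:
            stem = f"dissimilarity_p{dm.participant_id:02d}"
            side = pd.DataFrame(dm.values, index=dm.movement_codes, columns=dm.movement_codes)
            side.index.name = "movement"
            side.to_csv(out_dir / f"{stem}.csv", float_format="%.12g")
            masked = np.ma.masked_where(
                dm.values <= DISSIMILARITY_THRESHOLD, dm.values
            )
            fig, ax = plt.subplots(figsize=(4, 3.5))
            im = ax.imshow(masked, vmin=0, vmax=2, cmap="viridis")
            ax.set_xticks(range(len(dm.movement_codes)), dm.movement_codes)
            ax.set_yticks(range(len(dm.movement_codes)), dm.movement_codes)
            ax.set_title(f"P{dm.participant_id} dissimilarity (> {DISSIMILARITY_THRESHOLD} shown)")
            fig.colorbar(im)
            fig.savefig(out_dir / f"{stem}.{fmt}", dpi=100)
            plt.close(fig)
            written += [out_dir / f"{stem}.csv", out_dir / f"{stem}.{fmt}"]

    if classifications:
        for name, rep in classifications.items():
            stem = f"confusion_{name}"
            side = pd.DataFrame(rep.confusion, index=rep.classes, columns=rep.classes)
            side.index.name = "true"
            side.to_csv(out_dir / f"{stem}.csv")
            fig, ax = plt.subplots(figsize=(4, 3.5))
            im = ax.imshow(rep.confusion, cmap="Blues")
            for i in range(len(rep.classes)):
                for j in range(len(rep.classes)):
                    ax.text(j, i, rep.confusion[i, j], ha="center", va="center", fontsize=7)
            ax.set_xticks(range(len(rep.classes)), rep.classes)
            ax.set_yticks(range(len(rep.classes)), rep.classes)
            ax.set_title(f"{name}: accuracy {rep.accuracy:.1%}")
            fig.colorbar(im)
            fig.savefig(out_dir / f"{stem}.{fmt}", dpi=100)
            plt.close(fig)
            written += [out_dir / f"{stem}.csv", out_dir / f"{stem}.{fmt}"]

    logger.info("wrote %d report files to %s", len(written), out_dir)
    return written
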