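"""Spatial-pattern similarity and dissimilarity statistics.

The spatial fingerprint of a movement is its normalized 8-channel RMS
pattern.  For each participant ``i`` and movement ``m``, the 5 repetitions
x 3 windows give 15 patterns ``x_{i,m}(k)``; the block of 15 x 8 RMS
values is normalized by its maximum over repetitions and channels.

* Intra-subject similarity: mean Spearman rank correlation over all
  unordered pattern pairs ``(k, q)`` of a block — one aggregate ``r_{i,m}``
  per (participant, movement), 72 per session kind at full cohort size.
  Significance per block via a one-sided one-sample t-test (H0: mean <= 0)
  on the pairwise coefficients.
* Intra-task (inter-subject) similarity: per movement, each subject's 15
  patterns are averaged into one 8-vector (renormalized); the coefficient
  is the mean pairwise Spearman correlation over subject pairs.
* Inter-movement dissimilarity: per participant, ``1 - r`` between the
  mean patterns of movement pairs; values above 0.2 flag robustly distinct
  movements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureMatrix

DISSIMILARITY_THRESHOLD = 0.2
N_OBSERVATIONS = 15  # 5 repetitions x 3 windows


class InsufficientDataError(ValueError):
    pass


@dataclass
class RMSPattern:
    """One normalized 8-channel RMS pattern (one window of one repetition)."""

    participant_id: int
    movement_code: str
    observation_index: int  # 1..15
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (8,) or np.any(v < 0):
            raise ValueError("pattern must be 8 non-negative values")
        self.values = v


@dataclass
class SimilarityReport:
    """Pairwise and aggregate similarity of one (participant, movement) block."""

    participant_id: int
    movement_code: str
    pairwise: np.ndarray  # 15 x 15, diagonal 1, NaN where undefined
    aggregate: float
    p_value: float
    n_undefined_pairs: int = 0


@dataclass
class DissimilarityMatrix:
    """6 x 6 inter-movement dissimilarity (1 - r) for one participant."""

    participant_id: int
    movement_codes: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 2]

    @property
    def threshold_flag(self) -> np.ndarray:
        return self.values > DISSIMILARITY_THRESHOLD


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Ties receive average ranks (the coefficient is then the Pearson
    correlation of the ranks, which reduces to ``1 - 6 sum d^2 / (n(n^2-1))``
    when there are no ties).  A constant vector has no rank ordering:
    returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need two equal-length 1-d vectors, got {x.shape}, {y.shape}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.spearmanr(x, y).statistic
    return float(r)


def rms_patterns(fm: FeatureMatrix) -> list[RMSPattern]:
    """Block-normalized RMS patterns; 15 per complete (participant, movement).

    Control movements (codes 7-8) are excluded; incomplete blocks are
    skipped with a warning.
    """
    rms_cols = [f"RMS_ch{c}" for c in range(1, 9)]
    df = fm.df[~fm.df["movement_code"].str[1:].astype(int).isin([7, 8])]
    patterns: list[RMSPattern] = []
    for (pid, code), block in df.groupby(["participant_id", "movement_code"], sort=True):
        block = block.sort_values(["repetition_index", "window_index"])
        if len(block) != N_OBSERVATIONS:
            warnings.warn(
                f"participant {pid} movement {code}: {len(block)} observations "
                f"(expected {N_OBSERVATIONS}), block skipped",
                stacklevel=2,
            )
            continue
        vals = block[rms_cols].to_numpy(dtype=float)
        vmax = vals.max()
        if vmax > 0:
            vals = vals / vmax
        patterns.extend(
            RMSPattern(int(pid), str(code), k + 1, vals[k]) for k in range(len(vals))
        )
    return patterns


def _blocks(patterns: list[RMSPattern]) -> dict[tuple[int, str], np.ndarray]:
    out: dict[tuple[int, str], list[np.ndarray]] = {}
    for p in sorted(patterns, key=lambda p: (p.participant_id, p.movement_code, p.observation_index)):
        out.setdefault((p.participant_id, p.movement_code), []).append(p.values)
    return {k: np.vstack(v) for k, v in out.items()}


def similarity_significance(pairwise_values: np.ndarray) -> float:
    """One-sided one-sample t-test p-value for mean similarity > 0."""
    vals = np.asarray(pairwise_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise InsufficientDataError(
            f"need >= 3 finite similarity values, got {vals.size}"
        )
    if np.ptp(vals) == 0:  # zero variance: degenerate t statistic
        return 0.0 if vals[0] > 0 else 1.0
    return float(stats.ttest_1samp(vals, 0.0, alternative="greater").pvalue)


def intra_subject_similarity(patterns: list[RMSPattern]) -> list[SimilarityReport]:
    """Aggregate Spearman similarity per (participant, movement) block."""
    reports = []
    for (pid, code), block in _blocks(patterns).items():
        n = len(block)
        pw = np.eye(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, q in combinations(range(n), 2):
                pw[k, q] = pw[q, k] = spearman(block[k], block[q])
        upper = pw[np.triu_indices(n, 1)]
        finite = upper[np.isfinite(upper)]
        n_undef = upper.size - finite.size
        if n_undef:
            warnings.warn(
                f"participant {pid} movement {code}: {n_undef} undefined "
                "pairwise correlations excluded from the aggregate",
                stacklevel=2,
            )
        aggregate = float(finite.mean()) if finite.size else float("nan")
        p = similarity_significance(upper) if finite.size >= 3 else float("nan")
        reports.append(SimilarityReport(pid, code, pw, aggregate, p, n_undef))
    return reports


def _mean_pattern(block: np.ndarray) -> np.ndarray:
    m = block.mean(axis=0)
    return m / m.max() if m.max() > 0 else m


def intra_task_similarity(patterns: list[RMSPattern]) -> dict[str, float]:
    """Per movement: mean pairwise Spearman similarity across subjects.

    Each subject contributes one renormalized mean pattern.
    """
    blocks = _blocks(patterns)
    by_movement: dict[str, list[np.ndarray]] = {}
    for (pid, code), block in blocks.items():
        by_movement.setdefault(code, []).append(_mean_pattern(block))
    out = {}
    for code, means in sorted(by_movement.items()):
        if len(means) < 2:
            raise InsufficientDataError(
                f"movement {code}: need >= 2 subjects, got {len(means)}"
            )
        vals = [
            spearman(means[a], means[b]) for a, b in combinations(range(len(means)), 2)
        ]
        vals = np.asarray(vals)
        out[code] = float(vals[np.isfinite(vals)].mean())
    return out


def dissimilarity(patterns: list[RMSPattern]) -> list[DissimilarityMatrix]:
    """Per participant: 6 x 6 matrix of ``1 - r`` between mean movement patterns."""
    blocks = _blocks(patterns)
    by_pid: dict[int, dict[str, np.ndarray]] = {}
    for (pid, code), block in blocks.items():
        by_pid.setdefault(pid, {})[code] = _mean_pattern(block)
    out = []
    for pid, mean_by_code in sorted(by_pid.items()):
        codes = sorted(mean_by_code)
        n = len(codes)
        mat = np.zeros((n, n))
        for a, b in combinations(range(n), 2):
            r = spearman(mean_by_code[codes[a]], mean_by_code[codes[b]])
            mat[a, b] = mat[b, a] = 1.0 - r  # NaN propagates as missing
        out.append(DissimilarityMatrix(pid, codes, mat))
    return out


def similarity_table(reports: list[SimilarityReport]) -> pd.DataFrame:
    """Tidy table of per-block aggregates (one row per participant x movement)."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "movement_code": [r.movement_code for r in reports],
            "similarity": [r.aggregate for r in reports],
            "p_value": [r.p_value for r in reports],
            "n_undefined_pairs": [r.n_undefined_pairs for r in reports],
        }
    )
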