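"""Transcript-protein fold-change integration.

Each protein spot is paired with its gene's transcript, and the two log2
fold changes between a pair of cultivation conditions place the pair into
one of six classes (the sign convention is positive = more abundant in the
first-named condition):

* Q1 both up (>= hi), Q3 both down (<= -hi): concordant quadrants;
* Q2 protein up / transcript down, Q4 protein down / transcript up:
  discordant quadrants;
* T0 protein up while the transcript is flat (|transcript| <= lo),
  T-0 protein down while the transcript is flat;
* everything else is unclassified (including transcripts between lo and hi,
  which are neither differentially expressed nor flat).

Default cut-offs: hi = 0.6 (1.5-fold) and lo = 0.3 (1.2-fold) on the log2
scale.

The translational control efficiency ratio is
TCEr = 2^(protein_log2FC - transcript_log2FC); values above 3 (below 1/3)
flag proteins translated at least three times more (less) efficiently in
the first-named condition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("Q1", "Q2", "Q3", "Q4", "T0", "T-0", "unclassified")


class IntegrationError(ValueError):
    """Invalid input to the transcript-protein integration."""


def classify_pair(
    protein_log2fc: float,
    transcript_log2fc: float,
    hi: float = 0.6,
    lo: float = 0.3,
) -> str:
    """Figure-style quadrant/flat-transcript class of one pair."""
    p, t = float(protein_log2fc), float(transcript_log2fc)
    if not (math.isfinite(p) and math.isfinite(t)):
        raise IntegrationError("fold changes must be finite")
    if p >= hi and t >= hi:
        return "Q1"
    if p >= hi and t <= -hi:
        return "Q2"
    if p <= -hi and t <= -hi:
        return "Q3"
    if p <= -hi and t >= hi:
        return "Q4"
    if p >= hi and abs(t) <= lo:
        return "T0"
    if p <= -hi and abs(t) <= lo:
        return "T-0"
    return "unclassified"


def compute_tcer(
    protein_log2fc: float, transcript_log2fc: float
) -> tuple[float, str | None]:
    """TCEr and its flag ('high' if > 3, 'low' if < 1/3, else None)."""
    p, t = float(protein_log2fc), float(transcript_log2fc)
    if not (math.isfinite(p) and math.isfinite(t)):
        raise IntegrationError("fold changes must be finite")
    tcer = 2.0 ** (p - t)
    flag = "high" if tcer > 3.0 else ("low" if tcer < 1.0 / 3.0 else None)
    return tcer, flag


def classify_table(pairs: pd.DataFrame, hi: float = 0.6, lo: float = 0.3) -> pd.DataFrame:
    """Add class, tcer and tcer_flag columns to a pairs table.

    Expects columns protein_id, gene_id, comparison, protein_log2fc,
    transcript_log2fc; each spot (e.g. pI isoforms of one gene) is
    classified independently.
    """
    out = pairs.copy()
    out["class"] = [
        classify_pair(p, t, hi=hi, lo=lo)
        for p, t in zip(out["protein_log2fc"], out["transcript_log2fc"])
    ]
    tcers = [
        compute_tcer(p, t)
        for p, t in zip(out["protein_log2fc"], out["transcript_log2fc"])
    ]
    out["tcer"] = [t for t, _ in tcers]
    out["tcer_flag"] = [f or "" for _, f in tcers]
    return out


def class_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison counts of each class (rows sum to table size)."""
    counts = (
        classified.groupby(["comparison", "class"]).size().unstack(fill_value=0)
    )
    for c in CLASSES:
        if c not in counts.columns:
            counts[c] = 0
    return counts[list(CLASSES)]


def fc_correlation(pairs: pd.DataFrame) -> dict[str, float]:
    """Pearson and Spearman correlation of transcript vs protein log2FCs."""
    if len(pairs) < 3:
        raise IntegrationError("need at least 3 pairs")
    x = pairs["transcript_log2fc"].to_numpy(dtype=float)
    y = pairs["protein_log2fc"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise IntegrationError("fold changes must be finite")
    return {
        "pearson": float(stats.pearsonr(x, y).statistic),
        "spearman": float(stats.spearmanr(x, y).statistic),
    }
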