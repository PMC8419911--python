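"""Concordance of calls against a comparator assay, and PR/AUC evaluation.

The comparator is either a short-read sequencing call set (positivity rule:
comparator VRF strictly above 5% with at least 80x depth) or an assay with
explicit positive flags (droplet digital PCR style).  Every assessed locus
of every sample — the locus universe — is classified TP/FP/FN/TN, from
which sensitivity, specificity, precision and recall follow.  A
precision-recall curve is traced by sweeping the calculated-VAF cutoff of
the estimates, with saturated loci ranked above all finite estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AmpliconPanel
from .quant import VafEstimate

NGS_VRF_THRESHOLD = 0.05
NGS_MIN_DEPTH = 80


# ---------------------------------------------------------------------------
# Phred utilities
# ---------------------------------------------------------------------------

def phred_to_error(q: float) -> float:
    """Error rate for a phred score: e = 10^(-Q/10)."""
    if q < 0:
        raise ValueError("phred score must be >= 0")
    return 10.0 ** (-q / 10.0)


def error_to_phred(e: float) -> float:
    """Phred score for an error rate: Q = -10·log10(e)."""
    if not 0.0 < e <= 1.0:
        raise ValueError("error rate must be in (0, 1]")
    return -10.0 * math.log10(e)


# ---------------------------------------------------------------------------
# Comparator table
# ---------------------------------------------------------------------------

@dataclass
class ComparatorTable:
    """Comparator observations per (sample, amplicon, position).

    ``df`` columns: sample, amplicon, position, vrf, depth, positive.  In
    NGS mode positivity is derived (VRF > 5% and depth >= 80); in explicit
    mode the caller supplies the flags.
    """

    df: pd.DataFrame

    @classmethod
    def from_ngs(cls, df: pd.DataFrame) -> "ComparatorTable":
        df = df.copy()
        df["positive"] = (df["vrf"] > NGS_VRF_THRESHOLD) & \
                         (df["depth"] >= NGS_MIN_DEPTH)
        return cls(df)

    @classmethod
    def from_flags(cls, rows: list[tuple]) -> "ComparatorTable":
        """rows of (sample, amplicon, position, positive)."""
        df = pd.DataFrame(rows, columns=["sample", "amplicon", "position",
                                         "positive"])
        df["vrf"] = np.nan
        df["depth"] = np.nan
        return cls(df)

    def positives(self) -> set:
        pos = self.df[self.df["positive"]]
        return {(r.sample, r.amplicon, int(r.position))
                for r in pos.itertuples()}


# ---------------------------------------------------------------------------
# 2x2 concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceTable:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return math.nan  # undefined: no comparator positives
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            return math.nan
        return self.tn / (self.tn + self.fp)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return math.nan
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self.sensitivity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "comparator_pos": [self.tp, self.fn],
            "comparator_neg": [self.fp, self.tn],
        }, index=["called_pos", "called_neg"])


def concordance(
    called_loci: set,
    comparator_positives: set,
    universe: set,
) -> ConcordanceTable:
    """Classify every universe locus by the two call flags.

    ``called_loci`` and ``comparator_positives`` are sets of
    (sample, amplicon, position).  A called locus outside the universe is
    an error: silently admitting it would drift the denominators.
    """
    stray = called_loci - universe
    if stray:
        raise ValueError(
            f"{len(stray)} called locus/loci outside the assessed universe, "
            f"e.g. {sorted(stray)[0]!r}"
        )
    stray_comp = comparator_positives - universe
    if stray_comp:
        raise ValueError(
            f"{len(stray_comp)} comparator-positive locus/loci outside the "
            f"assessed universe"
        )
    tp = len(called_loci & comparator_positives)
    fp = len(called_loci - comparator_positives)
    fn = len(comparator_positives - called_loci)
    tn = len(universe) - tp - fp - fn
    return ConcordanceTable(tp=tp, fp=fp, fn=fn, tn=tn)


def calls_to_loci(table, called_only: bool = True) -> set:
    """Locus set of a :class:`~concatcall.calltable.CallTable`."""
    df = table.called if called_only else table.df
    return {(r.sample, r.amplicon, int(r.position)) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# Locus universe
# ---------------------------------------------------------------------------

def locus_universe(panel: AmpliconPanel, samples: list[str]):
    """All assessed loci across samples: the panel's enrichment-region
    positions crossed with the sample list.  Returns (count, set)."""
    panel_loci = panel.assessed_loci()
    universe = {(s, amp, pos) for s in samples for amp, pos in panel_loci}
    return len(panel_loci) * len(samples), universe


# ---------------------------------------------------------------------------
# Precision-recall curve
# ---------------------------------------------------------------------------

@dataclass
class PrCurve:
    cutoffs: np.ndarray   # descending; +inf for the saturated tier
    precision: np.ndarray
    recall: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "precision": self.precision,
            "recall": self.recall,
        })


def pr_curve(
    estimates: list[VafEstimate],
    comparator_positives: set,
) -> PrCurve:
    """Precision-recall tradeoff over the calculated-VAF cutoff.

    Saturated estimates rank above every finite estimate (their numeric
    VAF is not trusted).  The cutoff sweeps all distinct ranking values
    from high to low; the curve is anchored at recall 0 with the
    highest-cutoff precision and the AUC is the trapezoid integral over
    recall.  At the lowest cutoff every locus is predicted positive, so
    precision equals the comparator-positive prevalence.
    """
    if not estimates:
        raise ValueError("no estimates")
    keys = np.array([math.inf if e.saturated else e.vaf for e in estimates])
    labels = np.array([e.locus in comparator_positives for e in estimates])
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError(
            "degenerate comparator: need at least one positive and one "
            "negative among the assessed loci"
        )
    cutoffs = np.unique(keys)[::-1]  # descending
    precision, recall = [], []
    for c in cutoffs:
        predicted = keys >= c
        tp = int((predicted & labels).sum())
        precision.append(tp / int(predicted.sum()))
        recall.append(tp / n_pos)
    # Anchor at recall 0 with the most-stringent precision.
    precision = np.array([precision[0]] + precision)
    recall = np.array([0.0] + recall)
    auc = float(np.trapezoid(precision, recall))
    return PrCurve(cutoffs=cutoffs, precision=precision, recall=recall,
                   auc=auc)


def depth_stratified_discordance(
    comparator: ComparatorTable,
    pipeline_vrf: dict,
    vrf_cutoff: float = 0.20,
    bins: tuple = (0, 100, 200, 300, 500, 1000, np.inf),
) -> pd.DataFrame:
    """Histogram of comparator read depth for comparator-zero-VRF loci,
    with the fraction per depth bin where the pipeline VRF exceeded the
    cutoff.  ``pipeline_vrf`` maps (sample, amplicon, position) -> VRF."""
    zero = comparator.df[comparator.df["vrf"] == 0.0]
    depths = zero["depth"].to_numpy(dtype=float)
    keys = [(r.sample, r.amplicon, int(r.position)) for r in zero.itertuples()]
    hi = np.array([pipeline_vrf.get(k, 0.0) >= vrf_cutoff for k in keys])
    rows = []
    for lo, up in zip(bins[:-1], bins[1:]):
        in_bin = (depths >= lo) & (depths < up)
        n = int(in_bin.sum())
        rows.append({
            "depth_lo": lo, "depth_hi": up, "n_loci": n,
            "fraction_discordant": float(hi[in_bin].mean()) if n else math.nan,
        })
    return pd.DataFrame(rows)


def plot_pr_curve(curve: PrCurve, path) -> None:
    """Write a PR-curve plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.recall, curve.precision, marker="o", ms=3)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"AUC = {curve.auc * 100:.2f}%")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
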