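"""Enrichment-fold calibration and sample-VAF estimation.

Allele enrichment is modeled as a multiplicative fold ``E`` on variant
odds: a sample at VAF ``v`` sequences at an expected variant read fraction

    VRF = E·v/(1-v) / (1 + E·v/(1-v))

``E`` is calibrated from spike-in samples of known VAF by inverting this
relation, and original sample VAF is estimated from an observed VRF by the
inverse map.  VRFs near 1 saturate — the back-calculated VAF becomes
unreliable — so loci above a saturation VRF (default 90%) are classified
as high-VAF regardless of the numeric estimate.  High-VAF means an
estimated sample VAF above 5%, the clinically meaningful boundary for
treatment decisions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import enriched_fraction  # re-exported forward model

__all__ = [
    "CalibrationRecord", "VafEstimate", "calibrate_enrichment",
    "estimate_vaf", "mixture_vaf", "annotate_calls", "enriched_fraction",
]

HIGH_VAF_THRESHOLD = 0.05


@dataclass(frozen=True)
class CalibrationRecord:
    """One spike-in observation: known sample VAF and observed VRF."""

    locus: tuple
    vaf: float
    vrf: float

    @property
    def fold(self) -> float:
        """Single-record enrichment fold by the odds ratio."""
        return (self.vrf / (1.0 - self.vrf)) / (self.vaf / (1.0 - self.vaf))


@dataclass(frozen=True)
class VafEstimate:
    locus: tuple
    vrf: float
    fold: float
    vaf: float
    saturated: bool
    classification: str  # "high-VAF" | "low-VAF"
    indel_caveat: bool = False


def calibrate_enrichment(
    records: list[tuple[float, float]] | list[CalibrationRecord],
) -> float:
    """Enrichment fold from spike-in (VAF, VRF) records for one locus.

    Each record contributes the odds-ratio fold ``[VRF/(1-VRF)] /
    [VAF/(1-VAF)]``; multiple records are combined by geometric mean.
    Records with VAF 0/1 or VRF 0/1 carry infinite or zero odds and are
    excluded with a warning.
    """
    folds = []
    for rec in records:
        if isinstance(rec, CalibrationRecord):
            vaf, vrf = rec.vaf, rec.vrf
        else:
            vaf, vrf = rec
        if not (0.0 < vaf < 1.0) or not (0.0 < vrf < 1.0):
            warnings.warn(
                f"calibration record (VAF={vaf}, VRF={vrf}) has degenerate "
                "odds and is excluded",
                stacklevel=2,
            )
            continue
        folds.append((vrf / (1.0 - vrf)) / (vaf / (1.0 - vaf)))
    if not folds:
        raise ValueError("no usable calibration records")
    return float(np.exp(np.mean(np.log(folds))))


def estimate_vaf(
    vrf: float,
    fold: float,
    saturation_vrf: float = 0.90,
    locus: tuple = (),
    indel_caveat: bool = False,
) -> VafEstimate:
    """Estimate original sample VAF from an observed VRF.

    The inverse odds map divides the observed variant odds by the
    calibrated fold.  ``VRF > saturation_vrf`` marks the estimate as
    saturated and forces the high-VAF classification; otherwise high-VAF
    means an estimate above 5%.  ``fold`` must come from calibration — this
    function never guesses a default.
    """
    if not 0.0 <= vrf <= 1.0:
        raise ValueError(f"VRF must be in [0, 1], got {vrf}")
    if not fold > 0:
        raise ValueError(f"enrichment fold must be > 0, got {fold}")
    saturated = vrf > saturation_vrf
    if vrf == 1.0:
        vaf = 1.0
    else:
        odds = (vrf / (1.0 - vrf)) / fold
        vaf = odds / (1.0 + odds)
    if saturated:
        classification = "high-VAF"
    else:
        classification = "high-VAF" if vaf > HIGH_VAF_THRESHOLD else "low-VAF"
    return VafEstimate(
        locus=locus, vrf=vrf, fold=fold, vaf=vaf,
        saturated=saturated, classification=classification,
        indel_caveat=indel_caveat,
    )


def mixture_vaf(component_vafs, fractions) -> float:
    """Expected VAF of a mixture: the fraction-weighted mean of component
    VAFs (e.g. 1% of a 50%-VAF reference in 99% wildtype -> 0.5%)."""
    component_vafs = np.asarray(component_vafs, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if component_vafs.shape != fractions.shape:
        raise ValueError("component_vafs and fractions must align")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fractions.sum()}, expected 1")
    return float((component_vafs * fractions).sum())


def annotate_calls(table, panel, gate=None):
    """Fill estimated_vaf / saturated / classification on a call table.

    Loci without a calibrated fold on the panel stay unannotated (the
    estimator refuses to guess an enrichment fold).  Returns the table for
    chaining.
    """
    saturation = gate.saturation_vrf if gate is not None else 0.90
    df = table.df
    for idx, row in df.iterrows():
        fold = panel.fold_for(row["amplicon"], int(row["position"]),
                              str(row["variant"]))
        if fold is None:
            continue
        est = estimate_vaf(
            float(row["vrf"]), fold, saturation_vrf=saturation,
            indel_caveat=bool(row["indel_caveat"]),
        )
        df.loc[idx, "estimated_vaf"] = est.vaf
        df.loc[idx, "saturated"] = est.saturated
        df.loc[idx, "classification"] = est.classification
    return table


def read_calibration_tsv(path) -> dict:
    """Read a calibration TSV (amplicon, position, variant, known_vaf,
    observed_vrf) and return per-locus folds (geometric mean per locus)."""
    df = pd.read_csv(path, sep="\t")
    folds = {}
    for key, group in df.groupby(["amplicon", "position", "variant"]):
        records = [(float(r.known_vaf), float(r.observed_vrf))
                   for r in group.itertuples()]
        folds[(key[0], int(key[1]), key[2])] = calibrate_enrichment(records)
    return folds
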