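"""VRF statistics and dual-gate somatic variant calling.

The variant read fraction (VRF) at a position is the frequency of the most
frequent single-base change there — one of the three substitutions, an
insertion event anchored after the position, or a deletion of the position.
After allele enrichment a low-VAF somatic variant shows up as a high VRF,
so calling is a threshold rule; to suppress sequence-context error modes
(e.g. homopolymers) a second, independent confidence gate must also pass:

    called  <=>  VRF >= vrf_threshold  AND  score >= score_threshold
                 AND depth >= min_coverage AND locus not blacklisted
                 AND position inside the enrichment region

The confidence score is a pluggable provider.  The default maps a binomial
log-likelihood ratio (observed variant fraction vs. a sequencing-error
null) onto a 0-999 scale; an adapter can substitute scores parsed from an
external caller's VCF instead.

With a matched normal sample, per-position ΔVRF (tumor minus normal, for
the tumor's top variant) and robust z-scores quantify the excess of a
variant over the position-specific error background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import PileupMatrix, EVENT_ROWS
from .panel import AmpliconPanel
from .calltable import CallTable

_BASES = "ACGT"
#: Tie-break order of candidate events: substitutions by target base
#: (alphabetical), then insertion, then deletion.
_CANDIDATE_ROWS = [EVENT_ROWS["A"], EVENT_ROWS["C"], EVENT_ROWS["G"],
                   EVENT_ROWS["T"], EVENT_ROWS["ins"], EVENT_ROWS["del"]]


@dataclass
class GateConfig:
    """Thresholds of the dual-gate calling rule (defaults as calibrated:
    VRF >= 20%, score >= 180 on the 0-999 scale, coverage >= 50x; VRF above
    90% is treated as saturated for quantitation)."""

    vrf_threshold: float = 0.20
    score_threshold: float = 180.0
    min_coverage: int = 50
    saturation_vrf: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.vrf_threshold <= 1.0:
            raise ValueError("vrf_threshold must be in [0, 1]")
        if not 0.0 <= self.saturation_vrf <= 1.0:
            raise ValueError("saturation_vrf must be in [0, 1]")
        if self.min_coverage < 0 or self.score_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class VrfProfile:
    """Per-position top-variant profile of one pileup.

    Arrays are keyed by amplicon name and indexed by position.  ``region``
    is "primer" / "enrichment" / "other"; primer positions are masked from
    calling.  Zero-depth positions carry ``vrf = nan`` and are flagged, not
    dropped.
    """

    top_variant: dict[str, np.ndarray] = field(default_factory=dict)
    top_count: dict[str, np.ndarray] = field(default_factory=dict)
    vrf: dict[str, np.ndarray] = field(default_factory=dict)
    depth: dict[str, np.ndarray] = field(default_factory=dict)
    region: dict[str, np.ndarray] = field(default_factory=dict)
    low_coverage: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    ref: dict[str, str] = field(default_factory=dict)

    @property
    def amplicons(self) -> list[str]:
        return sorted(self.vrf)

    def event_fraction(self, amplicon: str, pos: int, variant: str) -> float:
        """Fraction of reads supporting ``variant`` at a position (any
        event, not only the top one); nan at zero depth."""
        depth = self.depth[amplicon][pos]
        if depth == 0:
            return math.nan
        row = _variant_row(variant)
        return float(self.counts[amplicon][row, pos] / depth)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for amp in self.amplicons:
            for pos in range(len(self.vrf[amp])):
                rows.append({
                    "amplicon": amp, "position": pos,
                    "ref": self.ref[amp][pos],
                    "top_variant": self.top_variant[amp][pos],
                    "vrf": self.vrf[amp][pos],
                    "depth": int(self.depth[amp][pos]),
                    "region": self.region[amp][pos],
                    "low_coverage": bool(self.low_coverage[amp][pos]),
                })
        return pd.DataFrame(rows)


def _variant_row(variant: str) -> int:
    if variant.startswith("ins"):
        return EVENT_ROWS["ins"]
    if variant == "del":
        return EVENT_ROWS["del"]
    return EVENT_ROWS[variant.split(">")[1]]


def vrf_profile(
    pileup: PileupMatrix,
    panel: AmpliconPanel,
    min_coverage: int = 50,
) -> VrfProfile:
    """Select the top non-reference event per position and compute its VRF.

    Tie-break among equal counts follows the fixed event order:
    substitutions alphabetical by target base, then insertion, then
    deletion.
    """
    profile = VrfProfile()
    for amp in panel.amplicons:
        counts = pileup.counts[amp.name]
        length = len(amp)
        depth = counts[:5].sum(axis=0)
        ref_codes = np.array([_BASES.index(b) for b in amp.sequence])
        cand = counts[_CANDIDATE_ROWS].astype(np.int64).copy()
        cand[ref_codes, np.arange(length)] = -1  # exclude the reference base
        top_idx = np.argmax(cand, axis=0)  # first max wins: the tie order
        top_count = cand[top_idx, np.arange(length)].clip(min=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vrf = np.where(depth > 0, top_count / np.maximum(depth, 1), np.nan)
        names = np.empty(length, dtype=object)
        for pos in range(length):
            idx = top_idx[pos]
            if idx < 4:
                names[pos] = f"{amp.sequence[pos]}>{_BASES[idx]}"
            elif idx == 4:
                names[pos] = "ins"
            else:
                names[pos] = "del"
        region = np.full(length, "other", dtype=object)
        for span, label in ((amp.forward_primer_span, "primer"),
                            (amp.reverse_primer_span, "primer"),
                            (amp.enrichment_region, "enrichment")):
            region[span[0]:span[1]] = label
        profile.top_variant[amp.name] = names
        profile.top_count[amp.name] = top_count
        profile.vrf[amp.name] = vrf
        profile.depth[amp.name] = depth
        profile.region[amp.name] = region
        profile.low_coverage[amp.name] = depth < min_coverage
        profile.counts[amp.name] = counts
        profile.ref[amp.name] = amp.sequence
    return profile


# ---------------------------------------------------------------------------
# Matched-normal ΔVRF
# ---------------------------------------------------------------------------

def delta_vrf(tumor: VrfProfile, normal: VrfProfile) -> pd.DataFrame:
    """Per-position ΔVRF (tumor top variant minus its frequency in the
    matched normal) with robust z-scores.

    z_i compares ΔVRF_i against the background of all other unmasked
    positions (global across amplicons): leave-one-out median and scaled
    MAD (1.4826·MAD estimates the SD of Gaussian noise).  Primer-region and
    zero-depth positions are excluded from the background and carry no z.
    """
    if set(tumor.vrf) != set(normal.vrf):
        raise ValueError("tumor and normal profiles cover different amplicons")
    rows = []
    for amp in tumor.amplicons:
        n_pos = len(tumor.vrf[amp])
        if n_pos != len(normal.vrf[amp]):
            raise ValueError(f"amplicon {amp!r}: profile lengths differ")
        for pos in range(n_pos):
            t_vrf = tumor.vrf[amp][pos]
            variant = tumor.top_variant[amp][pos]
            n_vrf = normal.event_fraction(amp, pos, variant)
            usable = (tumor.region[amp][pos] != "primer"
                      and not math.isnan(t_vrf) and not math.isnan(n_vrf))
            rows.append({
                "amplicon": amp, "position": pos, "variant": variant,
                "tumor_vrf": t_vrf, "normal_vrf": n_vrf,
                "delta_vrf": t_vrf - n_vrf if usable else math.nan,
                "usable": usable,
            })
    df = pd.DataFrame(rows)
    deltas = df.loc[df["usable"], "delta_vrf"].to_numpy()
    z = np.full(len(df), np.nan)
    usable_idx = np.flatnonzero(df["usable"].to_numpy())
    for rank, i in enumerate(usable_idx):
        rest = np.delete(deltas, rank)
        med = np.median(rest)
        mad = np.median(np.abs(rest - med))
        sd = 1.4826 * mad
        if sd > 0:
            z[i] = (deltas[rank] - med) / sd
    df["z"] = z
    return df.drop(columns="usable")


# ---------------------------------------------------------------------------
# Confidence score providers
# ---------------------------------------------------------------------------

def confidence_score(
    variant_count: int,
    depth: int,
    error_rate: float = 0.1,
    scale: float = 100.0,
) -> float:
    """Binomial log-likelihood-ratio confidence on a 0-999 scale.

    Compares the observed variant fraction against an error-rate null
    (reads showing the variant purely through sequencing error), in nats,
    multiplied by ``scale`` and clipped to [0, 999].  Monotone increasing
    in the variant count at fixed depth.
    """
    if depth <= 0:
        return 0.0
    p0 = min(max(error_rate, 1e-6), 0.999)
    p1 = variant_count / depth
    if p1 <= p0:
        return 0.0
    k, n = variant_count, depth
    llr = k * math.log(p1 / p0)
    if k < n:
        llr += (n - k) * math.log((1.0 - p1) / (1.0 - p0))
    else:
        llr += 0.0
    return float(min(max(scale * llr, 0.0), 999.0))


class LlrScoreProvider:
    """Default confidence gate: binomial LLR against an error-rate null.

    Fails closed below ``min_coverage`` (returns ``None``, so the score
    gate cannot pass).  With the default calibration a locus at VRF 0.2,
    depth 50 and a 10% error null scores above 180, mirroring the intended
    operating point of the score threshold.

    When constructed with the panel, the error null for insertion and
    deletion events is inflated by the homopolymer run length at the
    position: nanopore indel errors concentrate in homopolymers, and
    alignment anchors every deletion of a run onto the same reference
    position, so a run of length L accumulates roughly L times the
    per-base deletion error there.  This mirrors trained nanopore callers,
    which systematically score homopolymer indels low.
    """

    def __init__(self, error_rate: float = 0.1, scale: float = 100.0,
                 min_coverage: int = 50, panel: AmpliconPanel | None = None) -> None:
        self.error_rate = error_rate
        self.scale = scale
        self.min_coverage = min_coverage
        self.panel = panel

    def _null_rate(self, amplicon: str, position: int, variant: str) -> float:
        if self.panel is None or not (variant.startswith("ins")
                                      or variant == "del"):
            return self.error_rate
        seq = self.panel.get(amplicon).sequence
        run = max(_homopolymer_run_length(seq, position),
                  _homopolymer_run_length(seq, min(position + 1,
                                                   len(seq) - 1)))
        if run < 3:
            return self.error_rate
        return min(self.error_rate * run, 0.8)

    def score(self, amplicon: str, position: int, variant: str,
              variant_count: int, depth: int) -> float | None:
        if depth < self.min_coverage:
            return None
        return confidence_score(variant_count, depth,
                                self._null_rate(amplicon, position, variant),
                                self.scale)


def _homopolymer_run_length(seq: str, pos: int) -> int:
    """Length of the maximal homopolymer run containing ``seq[pos]``."""
    base = seq[pos]
    lo = pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = pos
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1


class VcfScoreProvider:
    """Adapter ingesting confidence scores from an external caller's VCF.

    Looks up QUAL by (amplicon, 0-based position, variant).  Loci absent
    from the VCF get no score (gate fails closed).
    """

    def __init__(self, path) -> None:
        self.scores: dict[tuple[str, int, str], float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, pos1, _id, ref, alt, qual = fields[:6]
                key = _vcf_to_locus(chrom, int(pos1), ref, alt)
                if key is not None and qual != ".":
                    self.scores[key] = float(qual)

    def score(self, amplicon: str, position: int, variant: str,
              variant_count: int, depth: int) -> float | None:
        key = (amplicon, position, variant)
        if key in self.scores:
            return self.scores[key]
        # Insertion events are matched ignoring the inserted sequence.
        if variant.startswith("ins"):
            for (amp, pos, var), score in self.scores.items():
                if amp == amplicon and pos == position and var.startswith("ins"):
                    return score
        return None


def _vcf_to_locus(chrom: str, pos1: int, ref: str, alt: str):
    if len(ref) == 1 and len(alt) == 1:
        return (chrom, pos1 - 1, f"{ref}>{alt}")
    if len(alt) > len(ref) == 1 and alt.startswith(ref):
        return (chrom, pos1 - 1, f"ins:{alt[1:]}")
    if len(ref) > len(alt) == 1 and ref.startswith(alt) and len(ref) == 2:
        return (chrom, pos1, "del")  # anchor at pos1 (1-based) => deleted base pos1 (0-based)
    return None


# ---------------------------------------------------------------------------
# Dual-gate calling
# ---------------------------------------------------------------------------

def call_variants(
    profile: VrfProfile,
    provider,
    gate: GateConfig,
    panel: AmpliconPanel,
    sample: str = "sample",
    report_min_vrf: float | None = None,
) -> CallTable:
    """Apply the dual-gate rule and emit a call table.

    A locus is called only when every gate passes; near-miss loci (VRF at
    or above ``report_min_vrf``, default the VRF threshold) stay in the
    table with their gate flags so that single-gate failures are auditable.
    """
    floor = gate.vrf_threshold if report_min_vrf is None else report_min_vrf
    rows = []
    for amp_name in profile.amplicons:
        amp = panel.get(amp_name)
        vrf = profile.vrf[amp_name]
        for pos in np.flatnonzero(np.nan_to_num(vrf, nan=-1.0) >= floor):
            pos = int(pos)
            variant = str(profile.top_variant[amp_name][pos])
            depth = int(profile.depth[amp_name][pos])
            count = int(profile.top_count[amp_name][pos])
            score = provider.score(amp_name, pos, variant, count, depth)
            pass_vrf = vrf[pos] >= gate.vrf_threshold
            pass_score = score is not None and score >= gate.score_threshold
            pass_cov = depth >= gate.min_coverage
            blacklisted = (amp_name, pos, variant) in panel.blacklist
            in_enrich = amp.in_enrichment(pos)
            rows.append({
                "sample": sample,
                "amplicon": amp_name,
                "position": pos,
                "ref_base": amp.sequence[pos],
                "variant": variant,
                "vrf": float(vrf[pos]),
                "coverage": depth,
                "score": score if score is not None else math.nan,
                "called": bool(pass_vrf and pass_score and pass_cov
                               and not blacklisted and in_enrich),
                "pass_vrf": bool(pass_vrf),
                "pass_score": bool(pass_score),
                "pass_coverage": bool(pass_cov),
                "blacklisted": bool(blacklisted),
                "in_enrichment": bool(in_enrich),
                "indel_caveat": variant.startswith("ins") or variant == "del",
                "estimated_vaf": math.nan,
                "saturated": False,
                "classification": "",
            })
    return CallTable.from_rows(rows) if rows else CallTable.empty()
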