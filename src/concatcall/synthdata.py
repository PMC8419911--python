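"""Synthetic panel builders for simulation, examples, and tests.

All panels produced here are synthetic: random reference sequences with
realistic amplicon geometry (a ~25 nt primer on each end flanking a
blocker-covered enrichment region).  They stand in for real cancer-gene
panels in simulation studies; no genomic sequence is embedded.
"""

from __future__ import annotations

import numpy as np

from .panel import Amplicon, AmpliconPanel
from .reads import CODE_BASES

DEFAULT_ADAPTER = None  # generated per panel from the seed


def random_dna(n: int, rng: np.random.Generator) -> str:
    return CODE_BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def random_panel(
    n_amplicons: int = 4,
    amplicon_length: int = 260,
    primer_length: int = 25,
    enrichment_margin: int = 5,
    enrichment_fold: float = 1000.0,
    adapter_length: int = 24,
    seed: int = 0,
) -> AmpliconPanel:
    """A synthetic panel of random amplicons with uniform geometry.

    Each amplicon is ``amplicon_length`` nt with primers at both ends and
    an enrichment region spanning the interior minus a small margin.
    Random sequences of this length are mutually ~75% divergent, so
    cross-mapping between amplicons is negligible.
    """
    rng = np.random.default_rng(seed)
    amplicons = []
    folds = {}
    for i in range(n_amplicons):
        name = f"AMP{i:02d}"
        seq = random_dna(amplicon_length, rng)
        start = primer_length + enrichment_margin
        end = amplicon_length - primer_length - enrichment_margin
        amplicons.append(Amplicon(
            name=name,
            sequence=seq,
            forward_primer_span=(0, primer_length),
            reverse_primer_span=(amplicon_length - primer_length,
                                 amplicon_length),
            enrichment_region=(start, end),
        ))
        folds[name] = enrichment_fold
    return AmpliconPanel(
        amplicons=amplicons,
        enrichment_fold=folds,
        junction_adapter=random_dna(adapter_length, rng),
    )


def melanoma_like_panel(seed: int = 0,
                        enrichment_fold: float = 1000.0) -> AmpliconPanel:
    """A synthetic 15-amplicon panel with melanoma-panel-scale geometry.

    Enrichment-region sizes are chosen so the panel assesses 384 loci in
    total (nine amplicons of 26 and six of 25 callable positions), the
    scale of a 15-plex melanoma hotspot panel.  Sequences are random.
    """
    rng = np.random.default_rng(seed)
    primer = 25
    amplicons = []
    folds = {}
    enrich_lengths = [26] * 9 + [25] * 6
    for i, elen in enumerate(enrich_lengths):
        name = f"MEL{i:02d}"
        length = int(rng.integers(220, 300))
        seq = random_dna(length, rng)
        start = (length - elen) // 2
        amplicons.append(Amplicon(
            name=name,
            sequence=seq,
            forward_primer_span=(0, primer),
            reverse_primer_span=(length - primer, length),
            enrichment_region=(start, start + elen),
        ))
        folds[name] = enrichment_fold
    return AmpliconPanel(
        amplicons=amplicons,
        enrichment_fold=folds,
        junction_adapter=random_dna(24, rng),
    )


def pick_snv_locus(panel: AmpliconPanel, amplicon: str,
                   offset: int = 5, alt: str | None = None):
    """A convenient SNV locus key inside an amplicon's enrichment region."""
    amp = panel.get(amplicon)
    pos = amp.enrichment_region[0] + offset
    ref = amp.sequence[pos]
    if alt is None:
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    return (amplicon, pos, f"{ref}>{alt}")
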