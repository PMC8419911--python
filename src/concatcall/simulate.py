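"""Synthetic data generator for enriched, concatemerized amplicon reads.

The generator emulates the three stages that shape real data upstream of the
bioinformatics pipeline:

1. **Allele-enriched monomer pool** — each monomer is a full copy of one
   panel amplicon; at each configured variant locus the monomer carries the
   variant with probability equal to the post-enrichment variant fraction
   predicted by the odds model (:func:`enriched_fraction`).  This models
   blocker-displacement PCR enrichment as a terminal fold ``E`` acting on
   allele odds rather than cycle-by-cycle amplification.
2. **Stochastic ligation into concatemers** — monomers are sampled uniformly
   without regard to amplicon identity and joined head-to-tail with a
   junction adapter between them (and a leading adapter), with the monomer
   count per concatemer drawn from a truncated geometric distribution
   reparameterized by its mean (default 13.5, the middle of the 12-15
   monomers/concatemer range observed by capillary electrophoresis).
3. **Nanopore-like read errors** — independent per-base substitution,
   insertion and deletion events, with the deletion rate inflated inside
   homopolymer runs of length >= 3.  Emitted base qualities are the phred
   equivalent of the configured total error rate.

All randomness flows from a single seed; stages draw from deterministic
substreams of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .panel import AmpliconPanel
from .reads import Read, ReadSet, revcomp, seq_to_codes, codes_to_seq

LocusKey = tuple[str, int, str]  # (amplicon, 0-based position, variant string)

MAX_MONOMERS = 40  # truncation bound of the monomer-count distribution


def variant_key(ref: str, alt: str) -> str:
    """Canonical variant string: ``R>A`` (SNV), ``ins:SEQ``, or ``del``."""
    ref, alt = ref.strip("-"), alt.strip("-")
    if len(ref) == 1 and len(alt) == 1:
        return f"{ref}>{alt}"
    if ref == "" and alt:
        return f"ins:{alt}"
    if alt == "" and len(ref) == 1:
        return "del"
    raise ValueError(f"unsupported variant ref={ref!r} alt={alt!r} "
                     "(SNV, single-anchor insertion, or 1-base deletion)")


def enriched_fraction(vaf: float, fold: float) -> float:
    """Expected post-enrichment variant read fraction under the odds model.

    Enrichment by fold ``E`` multiplies the variant/wildtype odds:
    ``VRF = E*v/(1-v) / (1 + E*v/(1-v))`` for sample VAF ``v``.  ``E = 1``
    is the identity; VAF 0 and 1 are preserved for any ``E``.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF must be in [0, 1], got {vaf}")
    if not fold > 0:
        raise ValueError(f"enrichment fold must be > 0, got {fold}")
    if vaf == 1.0:
        return 1.0
    odds = fold * vaf / (1.0 - vaf)
    return odds / (1.0 + odds)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    ``true_vaf`` maps locus keys to sample VAFs; ``enrichment_fold`` is
    either a scalar applied to every locus or a per-locus map.  Error rates
    are (substitution, insertion, deletion) per-base probabilities; the
    defaults total 7%, the concatemer read error rate regime (phred ~11.5);
    monomer-only regimes run closer to 10%.
    """

    true_vaf: dict[LocusKey, float] = field(default_factory=dict)
    enrichment_fold: float | dict[LocusKey, float] = 1.0
    n_reads: int = 1000
    monomer_mean: float = 13.5
    monomer_distribution: str = "truncated-geometric"  # or "fixed"
    error_rates: tuple[float, float, float] = (0.04, 0.015, 0.015)
    homopolymer_del_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for locus, vaf in self.true_vaf.items():
            if not 0.0 <= vaf <= 1.0:
                raise ValueError(f"VAF for {locus} must be in [0, 1]")
        for rate in self.error_rates:
            if not 0.0 <= rate < 1.0:
                raise ValueError("error rates must each be in [0, 1)")
        if sum(self.error_rates) >= 1.0:
            raise ValueError("error rates must sum to < 1")
        if self.monomer_mean < 1:
            raise ValueError("monomer_mean must be >= 1")
        if self.homopolymer_del_multiplier < 1:
            raise ValueError("homopolymer_del_multiplier must be >= 1")
        if isinstance(self.enrichment_fold, dict):
            folds = self.enrichment_fold.values()
        else:
            folds = [self.enrichment_fold]
        if any(not f > 0 for f in folds):
            raise ValueError("enrichment folds must be > 0")

    def fold_for(self, locus: LocusKey) -> float:
        if isinstance(self.enrichment_fold, dict):
            return float(self.enrichment_fold[locus])
        return float(self.enrichment_fold)

    @property
    def total_error_rate(self) -> float:
        return float(sum(self.error_rates))


@dataclass
class MonomerTruth:
    monomer_id: str
    amplicon: str
    strand: str
    variants: tuple[LocusKey, ...]  # loci at which this monomer is variant


@dataclass
class GroundTruth:
    """Simulation oracle: what each monomer is and where it ended up."""

    monomers: dict[str, MonomerTruth] = field(default_factory=dict)
    #: read id -> ordered list of monomer ids it contains
    reads: dict[str, list[str]] = field(default_factory=dict)
    #: locus -> expected post-enrichment variant fraction
    expected_fraction: dict[LocusKey, float] = field(default_factory=dict)

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    def monomer_counts(self) -> list[int]:
        return [len(v) for v in self.reads.values()]


# ---------------------------------------------------------------------------
# Stage 1: enriched monomer pool
# ---------------------------------------------------------------------------

def _apply_variant(seq: str, pos: int, variant: str) -> str:
    if variant.startswith("ins:"):
        return seq[: pos + 1] + variant[4:] + seq[pos + 1:]
    if variant == "del":
        return seq[:pos] + seq[pos + 1:]
    ref, alt = variant.split(">")
    if seq[pos] != ref:
        raise ValueError(
            f"variant {variant!r} at {pos}: reference base is {seq[pos]!r}"
        )
    return seq[:pos] + alt + seq[pos + 1:]


def simulate_monomers(
    panel: AmpliconPanel,
    config: SimulationConfig,
    n_monomers: int,
    rng: np.random.Generator | None = None,
    id_prefix: str = "mono",
) -> tuple[ReadSet, GroundTruth]:
    """Draw error-free monomers from the post-enrichment amplicon pool.

    Each monomer copies one amplicon chosen uniformly; each configured
    variant on that amplicon is present independently with probability
    ``enriched_fraction(VAF, E)``.  Strand is +/- with probability 1/2 and
    minus-strand monomers are reverse-complemented.  Variants placed in
    primer regions are rejected: blocker-displacement PCR cannot enrich
    there and primer positions are masked from calling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    by_amp: dict[str, list[tuple[int, str, float]]] = {a.name: [] for a in panel.amplicons}
    truth = GroundTruth()
    for (amp_name, pos, variant), vaf in config.true_vaf.items():
        amp = panel.get(amp_name)
        if amp.in_primer(pos):
            raise ValueError(
                f"variant {variant!r} at {amp_name}:{pos} lies in a primer "
                "region; enrichment cannot act there"
            )
        frac = enriched_fraction(vaf, config.fold_for((amp_name, pos, variant)))
        by_amp[amp_name].append((pos, variant, frac))
        truth.expected_fraction[(amp_name, pos, variant)] = frac
    # Apply higher-coordinate edits first so indels do not shift later loci.
    for entries in by_amp.values():
        entries.sort(key=lambda t: -t[0])

    amp_idx = rng.integers(0, len(panel.amplicons), size=n_monomers)
    minus = rng.random(n_monomers) < 0.5
    reads = ReadSet()
    for i in range(n_monomers):
        amp = panel.amplicons[int(amp_idx[i])]
        seq = amp.sequence
        carried = []
        for pos, variant, frac in by_amp[amp.name]:
            if rng.random() < frac:
                seq = _apply_variant(seq, pos, variant)
                carried.append((amp.name, pos, variant))
        strand = "-" if minus[i] else "+"
        if strand == "-":
            seq = revcomp(seq)
        mid = f"{id_prefix}{i}"
        reads.append(Read(
            id=mid,
            sequence=seq,
            qualities=np.full(len(seq), 40, dtype=np.int16),
            source_role="monomer-segment",
            strand=strand,
        ))
        truth.monomers[mid] = MonomerTruth(
            monomer_id=mid, amplicon=amp.name, strand=strand,
            variants=tuple(sorted(carried)),
        )
    return reads, truth


# ---------------------------------------------------------------------------
# Stage 2: concatemer assembly
# ---------------------------------------------------------------------------

def _truncated_geometric_p(mean: float) -> float:
    """Success probability of a geometric on {1..MAX_MONOMERS} with the
    requested mean (solved numerically; mean is monotone decreasing in p)."""
    ks = np.arange(1, MAX_MONOMERS + 1)

    def mean_of(p: float) -> float:
        w = (1.0 - p) ** (ks - 1)
        return float((ks * w).sum() / w.sum())

    lo, hi = 1e-9, 1.0 - 1e-9
    if mean >= mean_of(lo):
        return lo
    if mean <= mean_of(hi):
        return hi
    return float(brentq(lambda p: mean_of(p) - mean, lo, hi, xtol=1e-12))


def sample_monomer_counts(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Monomer counts per concatemer under the configured distribution."""
    if config.monomer_distribution == "fixed":
        return np.full(n, int(round(config.monomer_mean)), dtype=np.int64)
    if config.monomer_distribution != "truncated-geometric":
        raise ValueError(
            f"unknown monomer_distribution {config.monomer_distribution!r}"
        )
    p = _truncated_geometric_p(config.monomer_mean)
    ks = np.arange(1, MAX_MONOMERS + 1)
    w = (1.0 - p) ** (ks - 1)
    return rng.choice(ks, size=n, p=w / w.sum())


def assemble_concatemers(
    monomers: ReadSet,
    truth: GroundTruth,
    junction_adapter: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    counts: np.ndarray | None = None,
) -> tuple[ReadSet, GroundTruth]:
    """Ligate the monomer pool into concatemer reads.

    The pool is shuffled (stochastic incorporation of any amplicon) and
    consumed left to right; each concatemer takes ``k`` monomers with ``k``
    drawn from the configured distribution.  Read layout::

        adapter + monomer (+ adapter + monomer) * (k-1)

    The same junction adapter string serves as the leading adapter.  The
    trailing partial concatemer (if the pool does not divide evenly) is
    emitted as well.  ``truth.reads`` is filled with the monomer order of
    every concatemer.
    """
    if len(monomers) == 0:
        raise ValueError("monomer pool is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(monomers))
    pool = [monomers[int(i)] for i in order]
    if counts is None:
        counts = sample_monomer_counts(
            config, int(math.ceil(len(pool) / 1.0)), rng
        )
    adapter_q = np.full(len(junction_adapter), 40, dtype=np.int16)
    concatemers = ReadSet()
    i = 0
    read_no = 0
    for k in counts:
        if i >= len(pool):
            break
        chunk = pool[i: i + int(k)]
        i += int(k)
        rid = f"concat{read_no}"
        read_no += 1
        parts, quals = [], []
        for m in chunk:
            parts.append(junction_adapter)
            parts.append(m.sequence)
            quals.append(adapter_q)
            quals.append(m.qualities)
        concatemers.append(Read(
            id=rid,
            sequence="".join(parts),
            qualities=np.concatenate(quals) if quals else np.array([], np.int16),
            source_role="concatemer",
        ))
        truth.reads[rid] = [m.id for m in chunk]
    return concatemers, truth


# ---------------------------------------------------------------------------
# Stage 3: nanopore-like error model
# ---------------------------------------------------------------------------

def _homopolymer_mask(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs >= min_run."""
    n = len(codes)
    if n == 0:
        return np.zeros(0, dtype=bool)
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    boundary[1:] = codes[1:] != codes[:-1]
    run_id = np.cumsum(boundary) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def apply_error_model(
    reads: ReadSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Corrupt reads with independent per-base errors.

    Substitutions replace a base with a uniformly chosen different base;
    insertions add one random base after a position; deletions drop the
    base, with the deletion probability multiplied by
    ``homopolymer_del_multiplier`` inside homopolymer runs of length >= 3.
    Output qualities are constant at the phred equivalent of the total
    configured error rate.  Deterministic for a fixed generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    sub_rate, ins_rate, del_rate = config.error_rates
    total = config.total_error_rate
    if total == 0.0:
        return ReadSet(
            Read(r.id, r.sequence, r.qualities.copy(), r.source_role,
                 r.parent_read, r.strand, r.parent_span)
            for r in reads
        )
    qual = int(round(-10.0 * math.log10(total)))
    out = ReadSet()
    for r in reads:
        codes = seq_to_codes(r.sequence)
        n = len(codes)
        if n == 0:
            out.append(Read(r.id, "", np.array([], np.int16), r.source_role,
                            r.parent_read, r.strand, r.parent_span))
            continue
        del_p = np.full(n, del_rate)
        if config.homopolymer_del_multiplier > 1 and del_rate > 0:
            hp = _homopolymer_mask(codes)
            del_p[hp] = np.minimum(del_rate * config.homopolymer_del_multiplier,
                                   0.95)
        keep = rng.random(n) >= del_p
        sub = rng.random(n) < sub_rate
        ins = rng.random(n) < ins_rate

        mutated = codes.copy()
        if sub.any():
            shift = rng.integers(1, 4, size=int(sub.sum()), dtype=np.uint8)
            mutated[sub] = (mutated[sub] + shift) % 4
        counts = keep.astype(np.int64) + ins
        new = np.repeat(mutated, counts)
        if ins.any():
            # The last emitted copy for an ins position is the inserted base.
            slot = np.cumsum(counts) - 1
            ins_slots = slot[ins]
            new[ins_slots] = rng.integers(0, 4, size=len(ins_slots),
                                          dtype=np.uint8)
        out.append(Read(
            id=r.id,
            sequence=codes_to_seq(new),
            qualities=np.full(len(new), qual, dtype=np.int16),
            source_role=r.source_role,
            parent_read=r.parent_read,
            strand=r.strand,
        ))
    return out


# ---------------------------------------------------------------------------
# Convenience: full simulated sample
# ---------------------------------------------------------------------------

def simulate_run(
    panel: AmpliconPanel,
    config: SimulationConfig,
) -> tuple[ReadSet, GroundTruth]:
    """Simulate one sample end to end: enriched monomers -> concatemers ->
    error-corrupted reads.  ``config.n_reads`` is the concatemer read count.
    """
    if not panel.junction_adapter:
        raise ValueError("panel has no junction_adapter configured")
    root = np.random.SeedSequence(config.seed)
    rng_mono, rng_asm, rng_err = (np.random.default_rng(s)
                                  for s in root.spawn(3))
    counts = sample_monomer_counts(config, config.n_reads, rng_asm)
    n_monomers = int(counts.sum())
    monomers, truth = simulate_monomers(panel, config, n_monomers, rng_mono)
    concatemers, truth = assemble_concatemers(
        monomers, truth, panel.junction_adapter, config, rng_asm, counts
    )
    noisy = apply_error_model(concatemers, config, rng_err)
    return noisy, truth
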