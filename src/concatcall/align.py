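"""Panel-restricted alignment of monomer segments and pileup accumulation.

Segments are aligned semi-globally against each panel amplicon in both
orientations (edlib, unit-cost edit distance, free end gaps on the amplicon
so junction-truncated segments align where they fit).  The best-scoring
amplicon wins; ties between different amplicons are discarded as ambiguous
to avoid pseudogene-style cross-mapping.  Aligned segments are accumulated
into a per-amplicon, per-position event pileup (A/C/G/T, deletion,
insertion-after), the in-memory equivalent of a basecount table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .panel import AmpliconPanel
from .reads import Read, ReadSet, revcomp, seq_to_codes

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: Row layout of the pileup count matrix.
EVENT_ROWS = {"A": 0, "C": 1, "G": 2, "T": 3, "del": 4, "ins": 5}


@dataclass
class Alignment:
    """One segment aligned to one amplicon (amplicon-space coordinates)."""

    read: Read
    amplicon: str
    strand: str
    target_start: int
    target_end: int
    cigar: list[tuple[str, int]]  # extended ops: = X I D on oriented query
    edit_distance: int
    identity: float
    oriented_sequence: str  # query in amplicon-forward orientation

    def aligned_pairs(self):
        """Yield (query_pos, target_pos) pairs, ``None`` on the gap side,
        in pysam style.  Query positions index ``oriented_sequence``."""
        q, t = 0, self.target_start
        for op, length in self.cigar:
            if op in "=XM":
                for _ in range(length):
                    yield q, t
                    q += 1
                    t += 1
            elif op == "I":  # present in query, absent from amplicon
                for _ in range(length):
                    yield q, None
                    q += 1
            elif op == "D":  # absent from query, present in amplicon
                for _ in range(length):
                    yield None, t
                    t += 1


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def align_segment(
    segment: Read,
    panel: AmpliconPanel,
    min_identity: float = 0.7,
) -> Alignment | None:
    """Align one segment against all panel amplicons, both orientations.

    Returns ``None`` when no amplicon reaches ``min_identity`` or when two
    different amplicons tie on the best edit distance (ambiguous mapping is
    discarded rather than guessed).
    """
    seq = segment.sequence
    if not seq:
        return None
    rc = revcomp(seq)
    # Edit-distance budget: anything worse than this cannot reach
    # min_identity even in the best case.
    k = int(len(seq) * (1.0 - min_identity)) + 1
    best: tuple[int, str, str] | None = None  # (distance, amplicon, strand)
    ambiguous = False
    for amp in panel.amplicons:
        for strand, query in (("+", seq), ("-", rc)):
            res = edlib.align(query, amp.sequence, mode="HW",
                              task="distance", k=k)
            dist = res["editDistance"]
            if dist < 0:
                continue
            if best is None or dist < best[0]:
                best = (dist, amp.name, strand)
                ambiguous = False
                k = dist  # only accept strictly better or tying candidates
            elif dist == best[0] and amp.name != best[1]:
                ambiguous = True
    if best is None or ambiguous:
        return None
    dist, amp_name, strand = best
    amp = panel.get(amp_name)
    query = seq if strand == "+" else rc
    res = edlib.align(query, amp.sequence, mode="HW", task="path", k=dist)
    start, end_incl = res["locations"][0]
    cigar = _parse_cigar(res["cigar"])
    matches = sum(n for op, n in cigar if op == "=")
    columns = sum(n for _, n in cigar)
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    return Alignment(
        read=segment,
        amplicon=amp_name,
        strand=strand,
        target_start=start,
        target_end=end_incl + 1,
        cigar=cigar,
        edit_distance=dist,
        identity=identity,
        oriented_sequence=query,
    )


def align_readset(
    segments: ReadSet,
    panel: AmpliconPanel,
    min_identity: float = 0.7,
) -> tuple[list[Alignment], int]:
    """Align a whole segment set; returns alignments and the unaligned count."""
    alignments = []
    unaligned = 0
    for seg in segments:
        aln = align_segment(seg, panel, min_identity)
        if aln is None:
            unaligned += 1
        else:
            alignments.append(aln)
    return alignments, unaligned


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class PileupMatrix:
    """Per-amplicon event counts: rows A, C, G, T, del, ins per position.

    Column invariant: A + C + G + T + del == depth at every position
    (insertions are anchored events, not depth).
    """

    counts: dict[str, np.ndarray] = field(default_factory=dict)
    segment_count: dict[str, int] = field(default_factory=dict)

    @classmethod
    def zeros(cls, panel: AmpliconPanel) -> "PileupMatrix":
        return cls(
            counts={a.name: np.zeros((6, len(a)), dtype=np.int64)
                    for a in panel.amplicons},
            segment_count={a.name: 0 for a in panel.amplicons},
        )

    def depth(self, amplicon: str) -> np.ndarray:
        return self.counts[amplicon][:5].sum(axis=0)

    def base_count(self, amplicon: str, pos: int, event: str) -> int:
        return int(self.counts[amplicon][EVENT_ROWS[event], pos])

    def to_frame(self, panel: AmpliconPanel):
        import pandas as pd
        rows = []
        for amp in panel.amplicons:
            c = self.counts[amp.name]
            depth = self.depth(amp.name)
            for pos in range(len(amp)):
                rows.append({
                    "amplicon": amp.name, "position": pos,
                    "ref": amp.sequence[pos],
                    "A": c[0, pos], "C": c[1, pos], "G": c[2, pos],
                    "T": c[3, pos], "del": c[4, pos], "ins": c[5, pos],
                    "depth": depth[pos],
                })
        return pd.DataFrame(rows)


def add_alignment_to_pileup(pileup: PileupMatrix, aln: Alignment) -> None:
    counts = pileup.counts[aln.amplicon]
    qcodes = seq_to_codes(aln.oriented_sequence)
    q, t = 0, aln.target_start
    for op, length in aln.cigar:
        if op in "=XM":
            cols = np.arange(t, t + length)
            counts[qcodes[q:q + length], cols] += 1
            q += length
            t += length
        elif op == "I":
            # Event-level: one multi-base insertion counts once, anchored at
            # the reference position before the inserted bases.
            if t - 1 >= 0:
                counts[EVENT_ROWS["ins"], t - 1] += 1
            q += length
        elif op == "D":
            counts[EVENT_ROWS["del"], t:t + length] += 1
            t += length
    pileup.segment_count[aln.amplicon] += 1


def build_pileup(
    alignments: list[Alignment],
    panel: AmpliconPanel,
) -> PileupMatrix:
    """Accumulate aligned segments into a per-position event pileup."""
    pileup = PileupMatrix.zeros(panel)
    for aln in alignments:
        add_alignment_to_pileup(pileup, aln)
    return pileup


def downsample(
    alignments: list[Alignment],
    max_depth: int = 150,
    rng: np.random.Generator | int | None = None,
) -> list[Alignment]:
    """Cap per-amplicon coverage below ``max_depth`` segments.

    Amplicons whose aligned-segment count reaches the cap keep a uniform
    random subset of ``max_depth - 1`` segments (coverage strictly below the
    cap); others are untouched.  Deterministic for a fixed seed; output
    preserves input order.
    """
    if max_depth <= 0:
        raise ValueError("max_depth must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_amp: dict[str, list[int]] = {}
    for i, aln in enumerate(alignments):
        by_amp.setdefault(aln.amplicon, []).append(i)
    keep: set[int] = set()
    for amp in sorted(by_amp):
        idx = by_amp[amp]
        if len(idx) < max_depth:
            keep.update(idx)
        else:
            chosen = rng.choice(len(idx), size=max_depth - 1, replace=False)
            keep.update(idx[int(j)] for j in chosen)
    return [aln for i, aln in enumerate(alignments) if i in keep]


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileup: PileupMatrix, panel: AmpliconPanel,
                     path: str | Path) -> None:
    pileup.to_frame(panel).to_csv(path, sep="\t", index=False)


def write_sam(alignments: list[Alignment], panel: AmpliconPanel,
              path: str | Path) -> None:
    """Minimal SAM export of segment alignments in amplicon space."""
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for amp in panel.amplicons:
        lines.append(f"@SQ\tSN:{amp.name}\tLN:{len(amp)}")
    for aln in alignments:
        flag = 0 if aln.strand == "+" else 16
        cigar = "".join(f"{n}{op}" for op, n in aln.cigar)
        quals = aln.read.qualities
        if aln.strand == "-":
            quals = quals[::-1]
        qual_str = "".join(chr(min(int(q), 93) + 33) for q in quals) or "*"
        lines.append("\t".join([
            aln.read.id, str(flag), aln.amplicon, str(aln.target_start + 1),
            "60", cigar, "*", "0", "0", aln.oriented_sequence, qual_str,
            f"NM:i:{aln.edit_distance}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
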