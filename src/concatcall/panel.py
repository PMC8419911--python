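"""Amplicon panel model and panel-config I/O.

A panel bundles the reference amplicon sequences, their primer spans, the
blocker-covered enrichment region in which allele enrichment (and hence
variant calling) happens, the calibrated per-amplicon or per-locus
enrichment folds, a blacklist of loci excluded from calling (e.g. pseudogene
cross-amplification artifacts), and the junction adapter sequence that
separates monomers inside ligated concatemer reads.

Coordinates are 0-based half-open throughout; only VCF-like output is
1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

_DNA_RE = re.compile(r"^[ACGT]+$")


class PanelValidationError(ValueError):
    """Raised when a panel or panel config violates an invariant."""


@dataclass(frozen=True)
class Amplicon:
    """One reference amplicon with primer and enrichment-region annotation."""

    name: str
    sequence: str
    forward_primer_span: tuple[int, int]
    reverse_primer_span: tuple[int, int]
    enrichment_region: tuple[int, int]
    genome_anchor: tuple[str, int] | None = None  # (chrom, 1-based start)

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.sequence):
            raise PanelValidationError(
                f"amplicon {self.name!r}: sequence must contain only A/C/G/T"
            )
        n = len(self.sequence)
        for label, (start, end) in (
            ("forward_primer_span", self.forward_primer_span),
            ("reverse_primer_span", self.reverse_primer_span),
            ("enrichment_region", self.enrichment_region),
        ):
            if not (0 <= start < end <= n):
                raise PanelValidationError(
                    f"amplicon {self.name!r}: {label} {start}:{end} outside "
                    f"[0, {n})"
                )
        for label, span in (
            ("forward_primer_span", self.forward_primer_span),
            ("reverse_primer_span", self.reverse_primer_span),
        ):
            if _overlap(span, self.enrichment_region):
                raise PanelValidationError(
                    f"amplicon {self.name!r}: enrichment_region overlaps "
                    f"{label}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def in_primer(self, pos: int) -> bool:
        return (
            self.forward_primer_span[0] <= pos < self.forward_primer_span[1]
            or self.reverse_primer_span[0] <= pos < self.reverse_primer_span[1]
        )

    def in_enrichment(self, pos: int) -> bool:
        return self.enrichment_region[0] <= pos < self.enrichment_region[1]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class AmpliconPanel:
    """A multi-amplicon panel with enrichment calibration and blacklist.

    ``enrichment_fold`` maps an amplicon name (default) or a
    ``(amplicon, position, variant)`` locus key (override) to the calibrated
    fold E > 0.  Amplicons without a calibrated E are flagged, never filled
    with a guess.
    """

    amplicons: list[Amplicon]
    enrichment_fold: dict = field(default_factory=dict)
    blacklist: set = field(default_factory=set)
    junction_adapter: str = ""

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise PanelValidationError("amplicon names must be unique")
        for key, fold in self.enrichment_fold.items():
            if not fold > 0:
                raise PanelValidationError(
                    f"enrichment fold for {key!r} must be > 0, got {fold}"
                )
        by_name = {a.name: a for a in self.amplicons}
        for entry in self.blacklist:
            amp, pos, _variant = entry
            if amp not in by_name:
                raise PanelValidationError(
                    f"blacklist entry {entry!r}: unknown amplicon"
                )
            if not 0 <= pos < len(by_name[amp]):
                raise PanelValidationError(
                    f"blacklist entry {entry!r}: position outside amplicon"
                )
        if self.junction_adapter and not _DNA_RE.match(self.junction_adapter):
            raise PanelValidationError("junction_adapter must be A/C/G/T only")

    def __len__(self) -> int:
        return len(self.amplicons)

    def get(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]

    @property
    def shortest_amplicon(self) -> int:
        return min(len(a) for a in self.amplicons)

    def fold_for(self, amplicon: str, position: int, variant: str) -> float | None:
        """Calibrated enrichment fold for a locus: per-locus override first,
        then the amplicon default; ``None`` when uncalibrated."""
        key = (amplicon, position, variant)
        if key in self.enrichment_fold:
            return float(self.enrichment_fold[key])
        if amplicon in self.enrichment_fold:
            return float(self.enrichment_fold[amplicon])
        return None

    def missing_folds(self) -> list[str]:
        return [a.name for a in self.amplicons if a.name not in self.enrichment_fold]

    def assessed_loci(self) -> list[tuple[str, int]]:
        """All (amplicon, position) pairs eligible for calling: enrichment
        region positions (the blocker footprint) across the panel."""
        loci = []
        for a in self.amplicons:
            start, end = a.enrichment_region
            loci.extend((a.name, p) for p in range(start, end))
        return loci


# ---------------------------------------------------------------------------
# Panel config I/O: a single sectioned text file, one section per amplicon
# plus optional [panel], [blacklist] and [enrichment_fold] sections.
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\[(.+)\]$")


def _parse_span(value: str, where: str) -> tuple[int, int]:
    m = re.match(r"^(\d+):(\d+)$", value.strip())
    if not m:
        raise PanelValidationError(f"{where}: malformed interval {value!r}")
    return int(m.group(1)), int(m.group(2))


def read_panel(path: str | Path) -> AmpliconPanel:
    """Parse a panel config file.

    Format (0-based half-open intervals, ``start:end``)::

        [panel]
        junction_adapter = TGGTCTCAGGTA...

        [amplicon BRAF-600]
        sequence = ACGT...
        forward_primer = 0:25
        reverse_primer = 215:240
        enrichment_region = 30:210
        enrichment_fold = 1000
        chrom = chr7            # optional genome anchor
        genome_start = 140753301

        [blacklist]             # tab-separated: amplicon  pos  variant
        PIK3CA-542	57	G>A

        [enrichment_fold]       # per-locus overrides
        BRAF-600	88	A>T	850
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sections: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        m = _SECTION_RE.match(line.strip())
        if m:
            current = []
            sections.append((m.group(1).strip(), current))
        else:
            if current is None:
                raise PanelValidationError(
                    f"{path}: content before first section: {line!r}"
                )
            current.append(line)

    amplicons: list[Amplicon] = []
    enrichment_fold: dict = {}
    blacklist: set = set()
    junction_adapter = ""

    for header, lines in sections:
        if header.startswith("amplicon"):
            name = header[len("amplicon"):].strip()
            if not name:
                raise PanelValidationError(f"{path}: amplicon section without name")
            fields = _parse_kv(lines, f"amplicon {name!r}")
            for req in ("sequence", "forward_primer", "reverse_primer",
                        "enrichment_region"):
                if req not in fields:
                    raise PanelValidationError(
                        f"amplicon {name!r}: missing field {req!r}"
                    )
            anchor = None
            if "chrom" in fields and "genome_start" in fields:
                anchor = (fields["chrom"], int(fields["genome_start"]))
            amplicons.append(
                Amplicon(
                    name=name,
                    sequence=fields["sequence"].upper(),
                    forward_primer_span=_parse_span(
                        fields["forward_primer"], f"amplicon {name!r} forward_primer"
                    ),
                    reverse_primer_span=_parse_span(
                        fields["reverse_primer"], f"amplicon {name!r} reverse_primer"
                    ),
                    enrichment_region=_parse_span(
                        fields["enrichment_region"],
                        f"amplicon {name!r} enrichment_region",
                    ),
                    genome_anchor=anchor,
                )
            )
            if "enrichment_fold" in fields:
                enrichment_fold[name] = float(fields["enrichment_fold"])
        elif header == "panel":
            fields = _parse_kv(lines, "[panel]")
            junction_adapter = fields.get("junction_adapter", "").upper()
        elif header == "blacklist":
            for line in lines:
                parts = line.strip().split("\t")
                if len(parts) != 3:
                    raise PanelValidationError(
                        f"blacklist line must be 'amplicon<TAB>pos<TAB>variant': "
                        f"{line!r}"
                    )
                blacklist.add((parts[0], int(parts[1]), parts[2]))
        elif header == "enrichment_fold":
            for line in lines:
                parts = line.strip().split("\t")
                if len(parts) != 4:
                    raise PanelValidationError(
                        f"enrichment_fold line must be "
                        f"'amplicon<TAB>pos<TAB>variant<TAB>E': {line!r}"
                    )
                enrichment_fold[(parts[0], int(parts[1]), parts[2])] = float(parts[3])
        else:
            raise PanelValidationError(f"{path}: unknown section [{header}]")

    if not amplicons:
        raise PanelValidationError(f"{path}: no amplicon sections found")
    return AmpliconPanel(
        amplicons=amplicons,
        enrichment_fold=enrichment_fold,
        blacklist=blacklist,
        junction_adapter=junction_adapter,
    )


def _parse_kv(lines: list[str], where: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for line in lines:
        if "=" not in line:
            raise PanelValidationError(f"{where}: expected 'key = value': {line!r}")
        key, value = line.split("=", 1)
        fields[key.strip()] = value.strip()
    return fields


def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    """Write a panel config file that :func:`read_panel` round-trips."""
    out = []
    if panel.junction_adapter:
        out += ["[panel]", f"junction_adapter = {panel.junction_adapter}", ""]
    for a in panel.amplicons:
        out.append(f"[amplicon {a.name}]")
        out.append(f"sequence = {a.sequence}")
        out.append(f"forward_primer = {a.forward_primer_span[0]}:{a.forward_primer_span[1]}")
        out.append(f"reverse_primer = {a.reverse_primer_span[0]}:{a.reverse_primer_span[1]}")
        out.append(f"enrichment_region = {a.enrichment_region[0]}:{a.enrichment_region[1]}")
        if a.name in panel.enrichment_fold:
            out.append(f"enrichment_fold = {panel.enrichment_fold[a.name]:g}")
        if a.genome_anchor is not None:
            out.append(f"chrom = {a.genome_anchor[0]}")
            out.append(f"genome_start = {a.genome_anchor[1]}")
        out.append("")
    locus_folds = {
        k: v for k, v in panel.enrichment_fold.items() if isinstance(k, tuple)
    }
    if locus_folds:
        out.append("[enrichment_fold]")
        for (amp, pos, var), fold in sorted(locus_folds.items()):
            out.append(f"{amp}\t{pos}\t{var}\t{fold:g}")
        out.append("")
    if panel.blacklist:
        out.append("[blacklist]")
        for amp, pos, var in sorted(panel.blacklist):
            out.append(f"{amp}\t{pos}\t{var}")
        out.append("")
    Path(path).write_text("\n".join(out))


def write_reference_fasta(panel: AmpliconPanel, path: str | Path) -> None:
    """Export amplicon reference sequences as FASTA."""
    with open(path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f">{a.name}\n{a.sequence}\n")
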