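"""Variant call table: the tabular output of the calling stage.

Backed by a pandas DataFrame with a fixed column set.  Positions are 0-based
amplicon coordinates internally; the VCF-like writer emits 1-based POS.

Variant notation: substitutions as ``REF>ALT`` (e.g. ``G>T``), insertions as
``ins:SEQ`` (sequence inserted after the position), deletions as ``del``
(this reference position deleted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: Fixed column order of the TSV representation.
COLUMNS = [
    "sample",
    "amplicon",
    "position",
    "ref_base",
    "variant",
    "vrf",
    "coverage",
    "score",
    "called",
    "pass_vrf",
    "pass_score",
    "pass_coverage",
    "blacklisted",
    "in_enrichment",
    "indel_caveat",
    "estimated_vaf",
    "saturated",
    "classification",
]

_BOOL_COLS = [
    "called", "pass_vrf", "pass_score", "pass_coverage",
    "blacklisted", "in_enrichment", "indel_caveat", "saturated",
]


@dataclass
class CallTable:
    """Per-locus candidate variant calls with gate outcomes."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in COLUMNS:
            if col not in self.df.columns:
                self.df[col] = pd.NA
        self.df = self.df[COLUMNS].reset_index(drop=True)
        if len(self.df):
            vrf = self.df["vrf"].astype(float)
            if ((vrf < 0) | (vrf > 1)).any():
                raise ValueError("VRF outside [0, 1]")
            if (self.df["coverage"].astype(float) < 0).any():
                raise ValueError("negative coverage")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "CallTable":
        return cls(pd.DataFrame(columns=COLUMNS))

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "CallTable":
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    @property
    def called(self) -> pd.DataFrame:
        return self.df[self.df["called"] == True]  # noqa: E712

    def concat(self, other: "CallTable") -> "CallTable":
        return CallTable(pd.concat([self.df, other.df], ignore_index=True))


def write_calls(table: CallTable, path: str | Path, format: str = "tsv",
                panel=None) -> None:
    """Write a call table as TSV (all rows) or VCF-like (called rows).

    The VCF-like writer needs the panel to resolve reference bases for
    deletion records (REF spans the deleted base, ALT is the anchor base,
    per VCF convention) and emits 1-based positions.
    """
    if format == "tsv":
        table.df.to_csv(path, sep="\t", index=False)
    elif format == "vcf-like":
        _write_vcf_like(table, path, panel)
    else:
        raise ValueError(f"unknown call table format {format!r}")


def read_calls(path: str | Path) -> CallTable:
    df = pd.read_csv(path, sep="\t")
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    return CallTable(df)


def _write_vcf_like(table: CallTable, path: str | Path, panel) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=concatcall",
        '##INFO=<ID=VRF,Number=1,Type=Float,Description="Variant read fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">',
        '##INFO=<ID=EVAF,Number=1,Type=Float,Description="Estimated sample VAF">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, row in table.df.iterrows():
        if row["called"] != True:  # noqa: E712
            continue
        amplicon = row["amplicon"]
        pos0 = int(row["position"])
        variant = str(row["variant"])
        ref_base = str(row["ref_base"])
        if variant.startswith("ins:"):
            # Insertion after pos0: anchor base is REF, ALT = anchor + insert.
            ref, alt, pos_out = ref_base, ref_base + variant[4:], pos0 + 1
        elif variant == "del":
            # Deletion of pos0: anchor at pos0-1, REF spans the deleted base.
            if panel is None:
                raise ValueError("VCF-like deletion output requires the panel")
            seq = panel.get(amplicon).sequence
            if pos0 == 0:
                raise ValueError("cannot anchor a deletion at amplicon start")
            anchor = seq[pos0 - 1]
            ref, alt, pos_out = anchor + seq[pos0], anchor, pos0  # 1-based anchor
        else:
            ref, alt, pos_out = variant.split(">")[0], variant.split(">")[1], pos0 + 1
        score = row["score"]
        qual = f"{float(score):.0f}" if pd.notna(score) else "."
        info = f"VRF={float(row['vrf']):.4f};DP={int(row['coverage'])}"
        if pd.notna(row["estimated_vaf"]):
            info += f";EVAF={float(row['estimated_vaf']):.6f}"
        lines.append(
            f"{amplicon}\t{pos_out}\t.\t{ref}\t{alt}\t{qual}\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
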