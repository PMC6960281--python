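"""Design-table serialization: TSV, BED6 and FASTA carriers.

TSV coordinates are 1-based inclusive; BED follows the BED standard
(0-based half-open, strand in column 6); FASTA carries the targeting
sequence the sgRNA would contain, 5'->3'.
"""

from __future__ import annotations

import pandas as pd

from .design import DESIGN_COLUMNS

FORMATS = ("tsv", "bed", "fasta")


def _header_lines(provenance: dict | None) -> list[str]:
    return [f"# {k}: {(provenance or {})[k]}" for k in sorted(provenance or {})]


def write_candidates(
    table: pd.DataFrame, path, fmt: str = "tsv", provenance: dict | None = None
) -> None:
    """Write a design table in one of the supported formats.

    An empty table yields a valid empty file: header-only TSV, zero BED
    lines, zero FASTA records.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    with open(path, "w") as fh:
        if fmt == "tsv":
            for line in _header_lines(provenance):
                fh.write(line + "\n")
            out = table if len(table) else pd.DataFrame(columns=DESIGN_COLUMNS)
            out.to_csv(fh, sep="\t", index=False)
        elif fmt == "bed":
            for _, row in table.iterrows():
                name = f"{row.feature_id}|{row.system}|{row.targeting_sequence}"
                fh.write(
                    f"{row.contig}\t{row.start - 1}\t{row.end}\t{name}\t"
                    f"{row.seed_multiplicity}\t{row.proto_strand}\n"
                )
        else:
            for _, row in table.iterrows():
                fh.write(
                    f">{row.feature_id}|{row.system}|{row.contig}:"
                    f"{row.start}-{row.end}({row.proto_strand})\n"
                    f"{row.targeting_sequence}\n"
                )


def read_candidates_tsv(path) -> pd.DataFrame:
    """Read back a TSV design table, skipping provenance comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")
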