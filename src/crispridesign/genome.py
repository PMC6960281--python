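"""Genome and TSS-annotation I/O.

Coordinate conventions used throughout the package:

* **internal**: 0-based half-open intervals on the forward axis of each
  contig, regardless of strand;
* **user-facing TSV**: 1-based inclusive;
* **BED output**: 0-based half-open, per the BED standard.

Sequences are normalized to uppercase DNA over ``{A, C, G, T, N}``; ``U``
is transliterated to ``T``.  ``N`` is retained but is never matched by any
motif letter (including IUPAC ``N``): an ambiguous genome base cannot be
claimed as a determinate guide or PAM base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ``{A,C,G,T,N}`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceError(ValueError):
    """Malformed genome or annotation input."""


def normalize_sequence(raw: str, contig_id: str = "?") -> str:
    """Uppercase, U->T, and validate alphabet; report first bad offset."""
    seq = raw.upper().replace("U", "T")
    for offset, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise SequenceError(
                f"illegal residue {ch!r} in contig {contig_id!r} at offset {offset}"
            )
    return seq


@dataclass
class Genome:
    """An ordered collection of named DNA contigs.

    Parameters
    ----------
    contigs:
        Mapping contig id -> uppercase sequence over ``{A,C,G,T,N}``
        (insertion order is preserved and meaningful).
    topology:
        Per-contig ``"linear"`` or ``"circular"``.  Missing contigs default
        to linear.
    """

    contigs: dict[str, str]
    topology: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise SequenceError("genome has no contigs")
        total = 0
        for cid, seq in self.contigs.items():
            self.contigs[cid] = normalize_sequence(seq, cid)
            total += len(seq)
        if total == 0:
            raise SequenceError("genome has zero total length")
        for cid, topo in self.topology.items():
            if topo not in ("linear", "circular"):
                raise SequenceError(f"bad topology {topo!r} for contig {cid!r}")

    def is_circular(self, contig_id: str) -> bool:
        return self.topology.get(contig_id, "linear") == "circular"

    def length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig_id: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end), wrapping only on circular contigs.

        Returns ``None``-free text or raises if the interval runs off a
        linear contig.
        """
        seq = self.contigs[contig_id]
        n = len(seq)
        if 0 <= start <= end <= n:
            return seq[start:end]
        if not self.is_circular(contig_id):
            raise IndexError(
                f"interval [{start}, {end}) off linear contig {contig_id!r} (length {n})"
            )
        return "".join(seq[i % n] for i in range(start, end))


@dataclass(frozen=True)
class TssRecord:
    """One annotated transcription start site.

    ``tss_position`` is the 1-based coordinate of the first transcribed
    base; ``cds_start`` (optional) is the 1-based first base of the start
    codon.  A gene may carry several records (one per TSS).
    """

    feature_id: str
    contig_id: str
    tss_position: int
    strand: str
    operon_id: str | None = None
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SequenceError(
                f"strand must be + or -, got {self.strand!r} for {self.feature_id!r}"
            )
        if self.tss_position < 1:
            raise SequenceError(
                f"tss_position is 1-based and must be >= 1, got {self.tss_position}"
            )


def read_fasta(path, topology: dict[str, str] | None = None) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Header text up to the first whitespace becomes the contig id; multi-line
    records are concatenated; sequences are normalized to uppercase.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        cid = rec.id
        if cid in contigs:
            raise SequenceError(f"duplicate contig id {cid!r} in {path}")
        contigs[cid] = normalize_sequence(str(rec.seq), cid)
    if not contigs:
        raise SequenceError(f"no FASTA records in {path}")
    return Genome(contigs=contigs, topology=dict(topology or {}))


def write_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_TSS_ALIASES = {
    "feature_id": {"feature_id", "gene", "locus_tag", "feature"},
    "contig": {"contig", "contig_id", "chrom", "chr", "replicon"},
    "position": {"position", "tss", "tss_position", "pos"},
    "strand": {"strand"},
    "operon_id": {"operon_id", "operon"},
    "cds_start": {"cds_start", "cds", "start_codon"},
}


def read_tss_table(path, genome: Genome) -> list[TssRecord]:
    """Read a tab-separated TSS annotation table, validating against the genome.

    The header must name at least feature_id, contig, position and strand
    (common aliases accepted); '#' comment lines are ignored.  Multiple rows
    per feature are preserved.  Errors carry the 1-based line number.
    """
    records: list[TssRecord] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        header: dict[str, int] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                lowered = [c.strip().lower() for c in cells]
                header = {}
                for canon, aliases in _TSS_ALIASES.items():
                    for i, name in enumerate(lowered):
                        if name in aliases:
                            header[canon] = i
                            break
                missing = {"feature_id", "contig", "position", "strand"} - set(header)
                if missing:
                    raise SequenceError(
                        f"{path}:{lineno}: header missing column(s) {sorted(missing)}"
                    )
                continue

            def cell(canon: str) -> str | None:
                i = header.get(canon)
                if i is None or i >= len(cells):
                    return None
                v = cells[i].strip()
                return v or None

            fid = cell("feature_id")
            contig = cell("contig")
            pos_s = cell("position")
            strand = cell("strand")
            if not (fid and contig and pos_s and strand):
                raise SequenceError(f"{path}:{lineno}: incomplete row")
            if contig not in genome.contigs:
                raise SequenceError(f"{path}:{lineno}: unknown contig {contig!r}")
            try:
                pos = int(pos_s)
            except ValueError:
                raise SequenceError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            if not 1 <= pos <= genome.length(contig):
                raise SequenceError(
                    f"{path}:{lineno}: position {pos} outside contig {contig!r} "
                    f"(1-based, length {genome.length(contig)})"
                )
            if strand not in ("+", "-"):
                raise SequenceError(f"{path}:{lineno}: bad strand {strand!r}")
            key = (fid, pos, strand)
            if key in seen:
                raise SequenceError(
                    f"{path}:{lineno}: duplicate (feature, position, strand) {key}"
                )
            seen.add(key)
            cds_s = cell("cds_start")
            records.append(
                TssRecord(
                    feature_id=fid,
                    contig_id=contig,
                    tss_position=pos,
                    strand=strand,
                    operon_id=cell("operon_id"),
                    cds_start=int(cds_s) if cds_s is not None else None,
                )
            )
    return records


def write_tss_table(records: list[TssRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\toperon_id\tcontig\tposition\tstrand\tcds_start\n")
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.operon_id or ''}\t{r.contig_id}\t"
                f"{r.tss_position}\t{r.strand}\t{r.cds_start or ''}\n"
            )
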