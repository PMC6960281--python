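"""Degenerate PAM motif scanning and protospacer extraction.

A PAM (protospacer adjacent motif) is the short genomic motif a Cas9
protein requires immediately 3' of its protospacer.  This module
enumerates every occurrence of a system's IUPAC PAM motif on both genome
strands and extracts the fixed-length protospacer ending immediately 5'
of each occurrence.

All three systems handled here are type IIA Cas9s, so the PAM geometry is
fixed: the PAM lies 3' of the protospacer on the protospacer's strand.
Built-in systems:

* ``Sth3`` — S. thermophilus CRISPR3, PAM ``NGGNG``;
* ``Spa``  — S. pasteurianus, consensus PAM ``NNGTGA``.

S. pyogenes is supported through configuration only.  IUPAC letters in a
motif match their standard base sets; a genome ``N`` matches nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .genome import Genome, reverse_complement

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
#: Genome 'N' is deliberately absent from every set.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(motif: str) -> str:
    return motif.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_matches(motif: str, seq: str) -> bool:
    """Letter-for-letter IUPAC match of *seq* against *motif*."""
    return len(seq) == len(motif) and all(
        b in IUPAC[m] for m, b in zip(motif, seq)
    )


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(f"[{IUPAC[m]}]" for m in motif)
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class PamSpec:
    """One Cas9 system's PAM motif and guide architecture.

    ``scaffold`` is the crRNA direct repeat + tracrRNA DNA sequence used
    for construct assembly; it is configuration, not a shipped constant.
    """

    system_name: str
    pam_iupac: str
    protospacer_len: int = 20
    seed_len: int = 12
    scaffold: str | None = None

    def __post_init__(self) -> None:
        if not self.pam_iupac:
            raise ValueError("pam_iupac must be non-empty")
        bad = [c for c in self.pam_iupac.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in PAM {self.pam_iupac!r}")
        object.__setattr__(self, "pam_iupac", self.pam_iupac.upper())
        if self.protospacer_len <= 0:
            raise ValueError("protospacer_len must be positive")
        if not 0 < self.seed_len <= self.protospacer_len:
            raise ValueError("seed_len must satisfy 0 < seed_len <= protospacer_len")


#: Systems named in the source study.  Scaffolds are not shipped: the
#: repeat/tracrRNA sequences live on the reference plasmids, not here.
BUILTIN_SYSTEMS: dict[str, PamSpec] = {
    "Sth3": PamSpec("Sth3", "NGGNG"),
    "Spa": PamSpec("Spa", "NNGTGA"),
}


@dataclass(frozen=True)
class PamSite:
    """One genomic occurrence of a PAM motif.

    ``pam_interval`` is 0-based half-open on the forward axis;
    ``pam_sequence`` is read 5'->3' on the site's strand.
    """

    contig_id: str
    strand: str
    pam_start: int
    pam_end: int
    pam_sequence: str


@dataclass(frozen=True)
class Protospacer:
    """A candidate targeting sequence: the bases ending 5' of a PAM.

    ``targeting_sequence`` is read 5'->3' on the site's strand and is what
    the sgRNA spacer would contain; ``seed_sequence`` is its PAM-adjacent
    suffix (the portion whose exact match suffices for dCas9 binding).
    """

    site: PamSite
    proto_start: int
    proto_end: int
    targeting_sequence: str
    seed_sequence: str

    @property
    def contig_id(self) -> str:
        return self.site.contig_id

    @property
    def strand(self) -> str:
        return self.site.strand


@dataclass(frozen=True)
class Rejection:
    """Typed reason a PAM site yields no usable protospacer."""

    site: PamSite
    reason: str  # too_close_to_edge | ambiguous_base


def scan_pams(genome: Genome, spec: PamSpec, strands: str = "both") -> list[PamSite]:
    """Enumerate all PAM occurrences on the requested strand(s).

    Every length-``|pam|`` window matching the motif yields exactly one
    site; overlapping occurrences are all reported.  Minus-strand sites
    are found by scanning the forward sequence for the motif's reverse
    complement; their ``pam_sequence`` is reported 5'->3' on the minus
    strand.  On circular contigs windows crossing the origin are included.
    Result order is (contig order, forward-axis start, + before -).
    """
    if strands not in ("both", "forward", "reverse"):
        raise ValueError(f"strands must be both|forward|reverse, got {strands!r}")
    m = len(spec.pam_iupac)
    fwd_re = _motif_regex(spec.pam_iupac)
    rev_re = _motif_regex(iupac_reverse_complement(spec.pam_iupac))
    sites: list[PamSite] = []
    for cid, seq in genome.contigs.items():
        n = len(seq)
        scan_seq = seq + seq[: m - 1] if genome.is_circular(cid) and n >= m else seq
        contig_sites = []
        if strands in ("both", "forward"):
            for match in fwd_re.finditer(scan_seq):
                s = match.start()
                if s < n:
                    contig_sites.append(
                        PamSite(cid, "+", s, s + m, match.group(1))
                    )
        if strands in ("both", "reverse"):
            for match in rev_re.finditer(scan_seq):
                s = match.start()
                if s < n:
                    contig_sites.append(
                        PamSite(cid, "-", s, s + m, reverse_complement(match.group(1)))
                    )
        contig_sites.sort(key=lambda p: (p.pam_start, p.strand))
        sites.extend(contig_sites)
    return sites


def count_pams(genome: Genome, spec: PamSpec, strands: str = "both") -> int:
    """Number of PAM occurrences; both strands by default."""
    return len(scan_pams(genome, spec, strands))


def _upstream_window(site: PamSite, length: int) -> tuple[int, int]:
    """Forward-axis interval of the *length* bases 5' of the PAM on its strand."""
    if site.strand == "+":
        return site.pam_start - length, site.pam_start
    return site.pam_end, site.pam_end + length


def extract_upstream(genome: Genome, site: PamSite, length: int) -> tuple[int, int, str] | None:
    """The *length* bases ending 5' of the PAM, 5'->3' on the site's strand.

    Returns ``(start, end, sequence)`` with forward-axis coordinates, or
    ``None`` when the window runs off a linear contig.  On circular
    contigs the window wraps; its coordinates are then reported on the
    unrolled axis (start may be negative, end may exceed the contig
    length).  The sequence may contain ``N``; callers decide whether that
    disqualifies the window.
    """
    start, end = _upstream_window(site, length)
    n = genome.length(site.contig_id)
    if (start < 0 or end > n) and not genome.is_circular(site.contig_id):
        return None
    raw = genome.fetch(site.contig_id, start, end)
    seq = raw if site.strand == "+" else reverse_complement(raw)
    return start, end, seq


def extract_candidate(
    genome: Genome, site: PamSite, spec: PamSpec
) -> Protospacer | Rejection:
    """Extract the protospacer ending 5' of *site*, or a typed rejection.

    Rejections: ``too_close_to_edge`` when fewer than ``protospacer_len``
    bases exist 5' of the PAM on a linear contig; ``ambiguous_base`` when
    the window contains ``N``.
    """
    if site.contig_id not in genome.contigs:
        raise ValueError(f"site contig {site.contig_id!r} not in genome")
    got = extract_upstream(genome, site, spec.protospacer_len)
    if got is None:
        return Rejection(site, "too_close_to_edge")
    start, end, seq = got
    if "N" in seq:
        return Rejection(site, "ambiguous_base")
    return Protospacer(
        site=site,
        proto_start=start,
        proto_end=end,
        targeting_sequence=seq,
        seed_sequence=seq[-spec.seed_len :],
    )
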