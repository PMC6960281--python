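"""Guide selection in a window around transcription start sites.

CRISPRi knockdown works best when the sgRNA base-pairs with the
nontemplate (coding) strand near the 5' end of the transcript.  This
module searches a window spanning, at the defaults, 50 bases upstream to
100 bases downstream of each annotated TSS for protospacers whose sgRNA
would target the nontemplate strand, annotates each candidate with its
TSS offset and seed uniqueness, and assembles the genome-wide design
table.

Strand semantics: the sgRNA's sequence equals the protospacer.  It
base-pairs with (is complementary to) the nontemplate strand exactly when
the protospacer lies on the gene's template strand, i.e. the genomic
strand *opposite* the annotated gene strand.  Hence
``targeting_class == "nontemplate"`` iff protospacer strand != gene strand.

Offset convention: offsets are transcript-oriented; offset 0 is the TSS
base itself, -50 is the 50th base upstream, and the downstream bound is
exclusive.  ``tss_offset`` of a candidate is the offset of the
protospacer base nearest the TSS (0 when the protospacer covers the TSS).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import pandas as pd

from .genome import Genome, TssRecord
from .pam import PamSpec, Protospacer, extract_candidate, scan_pams
from .seeds import SeedIndex, build_seed_index, seed_multiplicity

DEFAULT_UPSTREAM = -50
DEFAULT_DOWNSTREAM = 100


@dataclass(frozen=True)
class TranscriptWindow:
    """A TSS-anchored search window mapped onto the forward axis.

    ``start``/``end`` are 0-based half-open forward-axis coordinates,
    already clipped to the contig; an empty interval is valid.
    """

    tss: TssRecord
    upstream_offset: int
    downstream_offset: int
    start: int
    end: int

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end and start <= end


def transcript_window(
    tss: TssRecord,
    genome: Genome,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> TranscriptWindow:
    """Orient [upstream, downstream) along transcription and clip to the contig.

    For a + strand TSS at 1-based position p the forward-axis interval is
    [p-1+upstream, p-1+downstream); for a - strand TSS it is
    [p-downstream, p-upstream).  A window entirely off-contig comes back
    empty, not as an error.
    """
    if upstream >= downstream:
        raise ValueError("upstream offset must be < downstream offset")
    p = tss.tss_position
    if tss.strand == "+":
        start, end = p - 1 + upstream, p - 1 + downstream
    else:
        start, end = p - downstream, p - upstream
    n = genome.length(tss.contig_id)
    start, end = max(start, 0), min(end, n)
    if start > end:
        start = end
    return TranscriptWindow(tss, upstream, downstream, start, end)


def classify_targeting_strand(protospacer_strand: str, gene_strand: str) -> str:
    """``nontemplate`` when the sgRNA pairs with the nontemplate strand.

    That is the case when the protospacer lies opposite the gene strand.
    """
    for s in (protospacer_strand, gene_strand):
        if s not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {s!r}")
    return "nontemplate" if protospacer_strand != gene_strand else "template"


@dataclass(frozen=True)
class GuideCandidate:
    """One protospacer annotated with its TSS context and uniqueness verdict."""

    protospacer: Protospacer
    tss: TssRecord
    system_name: str
    targeting_class: str
    tss_offset: int
    seed_multiplicity: int
    unique: bool
    beyond_cds_start: bool | None  # None when the annotation has no cds_start

    @property
    def feature_id(self) -> str:
        return self.tss.feature_id


def _transcript_coord(tss: TssRecord, forward_pos: int) -> int:
    """Transcript-oriented offset of a 0-based forward-axis position."""
    p0 = tss.tss_position - 1
    return forward_pos - p0 if tss.strand == "+" else p0 - forward_pos

def _annotate(proto: Protospacer, tss: TssRecord, spec: PamSpec, index: SeedIndex) -> GuideCandidate:
    lo = _transcript_coord(tss, proto.proto_start)
    hi = _transcript_coord(tss, proto.proto_end - 1)
    lo, hi = min(lo, hi), max(lo, hi)
    offset = 0 if lo <= 0 <= hi else (lo if lo > 0 else hi)
    beyond: bool | None = None
    if tss.cds_start is not None:
        beyond = hi >= _transcript_coord(tss, tss.cds_start - 1)
    mult = seed_multiplicity(index, proto)
    return GuideCandidate(
        protospacer=proto,
        tss=tss,
        system_name=spec.system_name,
        targeting_class=classify_targeting_strand(proto.strand, tss.strand),
        tss_offset=offset,
        seed_multiplicity=mult,
        unique=mult == 1,
        beyond_cds_start=beyond,
    )


def design_for_tss(
    genome: Genome,
    tss: TssRecord,
    spec: PamSpec,
    index: SeedIndex,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    class_filter: str = "nontemplate",
    require_pam_in_window: bool = False,
    _sites=None,
    _starts=None,
) -> list[GuideCandidate]:
    """All guide candidates for one TSS, nearest-to-TSS first.

    The full protospacer must lie inside the window; by default the PAM
    may extend past either edge (``require_pam_in_window`` tightens
    this).  Order: |tss_offset| ascending, then forward-axis start, then
    + strand before -.
    """
    if class_filter not in ("nontemplate", "all"):
        raise ValueError(f"class filter must be nontemplate|all, got {class_filter!r}")
    window = transcript_window(tss, genome, upstream, downstream)
    sites = _sites if _sites is not None else scan_pams(genome, spec, "both")
    # sites are sorted by pam_start; only those within a protospacer's
    # reach of the window can yield an in-window candidate
    margin = spec.protospacer_len + len(spec.pam_iupac)
    starts = _starts if _starts is not None else [s.pam_start for s in sites]
    lo = bisect_left(starts, window.start - margin)
    hi = bisect_right(starts, window.end + margin)
    out: list[GuideCandidate] = []
    for site in sites[lo:hi]:
        if site.contig_id != tss.contig_id:
            continue
        proto = extract_candidate(genome, site, spec)
        if not isinstance(proto, Protospacer):
            continue
        if not window.contains(proto.proto_start, proto.proto_end):
            continue
        if require_pam_in_window and not window.contains(site.pam_start, site.pam_end):
            continue
        cand = _annotate(proto, tss, spec, index)
        if class_filter == "nontemplate" and cand.targeting_class != "nontemplate":
            continue
        out.append(cand)
    out.sort(
        key=lambda c: (
            abs(c.tss_offset),
            c.protospacer.proto_start,
            0 if c.protospacer.strand == "+" else 1,
        )
    )
    return out


DESIGN_COLUMNS = [
    "feature_id", "operon_id", "system", "contig", "gene_strand",
    "tss_position", "proto_strand", "targeting_class", "start", "end",
    "tss_offset", "targeting_sequence", "seed_sequence",
    "seed_multiplicity", "unique", "beyond_cds_start",
    "pam_sequence", "pam_start", "pam_end",
]


def candidates_to_table(candidates: list[GuideCandidate]) -> pd.DataFrame:
    """Flatten candidates into the design table (1-based inclusive coordinates)."""
    rows = []
    for c in candidates:
        p = c.protospacer
        rows.append({
            "feature_id": c.tss.feature_id,
            "operon_id": c.tss.operon_id or "",
            "system": c.system_name,
            "contig": p.contig_id,
            "gene_strand": c.tss.strand,
            "tss_position": c.tss.tss_position,
            "proto_strand": p.strand,
            "targeting_class": c.targeting_class,
            "start": p.proto_start + 1,
            "end": p.proto_end,
            "tss_offset": c.tss_offset,
            "targeting_sequence": p.targeting_sequence,
            "seed_sequence": p.seed_sequence,
            "seed_multiplicity": c.seed_multiplicity,
            "unique": c.unique,
            "beyond_cds_start": "" if c.beyond_cds_start is None else c.beyond_cds_start,
            "pam_sequence": p.site.pam_sequence,
            "pam_start": p.site.pam_start + 1,
            "pam_end": p.site.pam_end,
        })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def design_genome_wide(
    genome: Genome,
    tss_records: list[TssRecord],
    specs: list[PamSpec],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    class_filter: str = "nontemplate",
    require_pam_in_window: bool = False,
    indexes: dict[str, SeedIndex] | None = None,
) -> pd.DataFrame:
    """Design every TSS against every system; one row per (candidate, TSS, system).

    Each TSS of a multi-TSS gene is designed independently; gene-level
    aggregation happens in the targetability report.  The output order is
    deterministic: systems in the given order, TSS records in input order,
    candidates nearest-to-TSS first.
    """
    all_candidates: list[GuideCandidate] = []
    for spec in specs:
        index = (indexes or {}).get(spec.system_name) or build_seed_index(genome, spec)
        sites = scan_pams(genome, spec, "both")
        by_contig: dict[str, list] = {}
        for s in sites:
            by_contig.setdefault(s.contig_id, []).append(s)
        starts_by_contig = {
            cid: [s.pam_start for s in lst] for cid, lst in by_contig.items()
        }
        for tss in tss_records:
            all_candidates.extend(
                design_for_tss(
                    genome, tss, spec, index,
                    upstream=upstream, downstream=downstream,
                    class_filter=class_filter,
                    require_pam_in_window=require_pam_in_window,
                    _sites=by_contig.get(tss.contig_id, []),
                    _starts=starts_by_contig.get(tss.contig_id, []),
                )
            )
    return candidates_to_table(all_candidates)
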