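"""Deterministic synthetic fixtures: genomes, TSS tables, planted guide
sites and synthetic SAM alignments.

These fixtures emulate the shape of a GC-rich bacterial genome (~67% GC)
with annotated transcription start sites and PAM-adjacent protospacers
planted at known locations, so the whole design pipeline can be
exercised and checked against a planting ledger without any download.
They do not simulate realistic transcriptomes, sequencing error or
operonic structure beyond what the ledger records.

Randomness comes from ``numpy.random.default_rng`` (PCG64), so the same
seed reproduces the same bytes on any platform.  Planted PAMs use the
least-degenerate concrete instantiation of the motif (N -> A), e.g.
``AGGAG`` for ``NGGNG``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genome import Genome, TssRecord, reverse_complement, write_fasta, write_tss_table
from .pam import BUILTIN_SYSTEMS, IUPAC, PamSpec

PROFILES = ("minimal", "coverage-demo", "rnaseq-demo")

_BASES = np.array(list("ACGT"))


def generate_genome(
    length: int, gc: float, seed: int | None = None,
    rng: np.random.Generator | None = None, contig_id: str = "synthchr1",
) -> Genome:
    """I.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if length <= 0:
        raise ValueError("length must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return Genome(contigs={contig_id: seq})


def concrete_pam(spec: PamSpec) -> str:
    """Least-degenerate instantiation of the motif (first base of each set)."""
    return "".join(IUPAC[c][0] for c in spec.pam_iupac)


@dataclass
class PlantedSite:
    """Ledger entry: where a guide site was written and what to expect."""

    system: str
    contig_id: str
    feature_id: str | None
    gene_strand: str
    site_strand: str
    proto_start: int  # 0-based half-open, forward axis
    proto_end: int
    pam_start: int
    pam_end: int
    targeting_sequence: str
    seed_sequence: str
    expected_class: str
    expected_unique: bool
    decoy_start: int | None = None  # second PAM-adjacent seed copy, if planted


def _site_strand(gene_strand: str, desired_class: str) -> str:
    flip = {"+": "-", "-": "+"}
    return flip[gene_strand] if desired_class == "nontemplate" else gene_strand


def _local_matches(text: str, spec: PamSpec) -> list[tuple[int, str]]:
    """All (start, strand) motif occurrences in *text*, both strands."""
    from .pam import _motif_regex, iupac_reverse_complement

    out = [(m.start(), "+") for m in _motif_regex(spec.pam_iupac).finditer(text)]
    rc = _motif_regex(iupac_reverse_complement(spec.pam_iupac))
    out += [(m.start(), "-") for m in rc.finditer(text)]
    return sorted(out)


class FixturePlanter:
    """Mutable genome under construction, with collision-aware planting.

    Planted-set recovery demands that the only PAM-adjacent candidates
    inside a design window are the planted ones, so the planter supports
    *protected zones* (window neighborhoods) from which background motif
    occurrences are scrubbed before planting, and it re-rolls any
    protospacer whose insertion would create an incidental motif.
    """

    def __init__(self, genome: Genome, rng: np.random.Generator):
        (self.contig_id, seq), = genome.contigs.items()
        self.seq = list(seq)
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []
        self.protected: list[tuple[int, int]] = []
        self.intended_pams: set[tuple[int, str]] = set()
        self.ledger: list[PlantedSite] = []
        self.tss_records: list[TssRecord] = []

    def _collides(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.occupied)

    def _is_occupied(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.occupied)

    def _in_protected(self, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.protected)

    def _write(self, start: int, text: str) -> None:
        self.seq[start : start + len(text)] = list(text)
        self.occupied.append((start, start + len(text)))

    def _random_protospacer(self, length: int) -> str:
        return "".join(self.rng.choice(_BASES, size=length))

    def protect_window(self, spec: PamSpec, start: int, end: int) -> None:
        """Mark [start, end) plus a protospacer+PAM margin as a zone that
        must contain no background PAM occurrences."""
        margin = spec.protospacer_len + len(spec.pam_iupac)
        n = len(self.seq)
        self.protected.append((max(0, start - margin), min(n, end + margin)))

    def _break_positions(self, spec: PamSpec, s: int, strand: str):
        """Yield (forward position, replacement base) choices that break a
        motif occurrence at (s, strand) — constrained motif letters only."""
        motif = spec.pam_iupac
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for j, code in enumerate(motif):
            if len(IUPAC[code]) == 4:
                continue  # mutating a fully degenerate position cannot break it
            if strand == "+":
                pos = s + j
                allowed = sorted(set("ACGT") - set(IUPAC[code]))
            else:
                pos = s + len(motif) - 1 - j
                allowed = sorted(set("ACGT") - {comp[b] for b in IUPAC[code]})
            yield pos, allowed[0]

    def scrub(self, spec: PamSpec, max_rounds: int = 50) -> int:
        """Mutate unintended motif occurrences out of all protected zones.

        Deterministic (no randomness); never touches planted blocks or the
        intended planted PAMs; iterates to a fixpoint because a mutation
        can itself create a new occurrence.  Returns bases changed.
        """
        changed = 0
        for _ in range(max_rounds):
            text = "".join(self.seq)
            dirty = False
            for s, strand in _local_matches(text, spec):
                e = s + len(spec.pam_iupac)
                if not self._in_protected(s, e) or (s, strand) in self.intended_pams:
                    continue
                for pos, base in self._break_positions(spec, s, strand):
                    if not self._is_occupied(pos):
                        self.seq[pos] = base
                        changed += 1
                        dirty = True
                        break
                else:
                    raise RuntimeError(
                        "unbreakable motif occurrence inside a planted block"
                    )
            if not dirty:
                return changed
        raise RuntimeError("scrub did not converge")

    def _insertion_is_scrubbable(self, spec: PamSpec, pos: int, block: str,
                                 intended: tuple[int, str]) -> bool:
        """True if placing *block* at *pos* creates no unwanted motif
        occurrence that could not later be scrubbed from flank bases.

        An occurrence whose every constrained position falls inside the
        block (or an older planted block) is unbreakable without touching
        planted bases, so the caller must re-roll the protospacer.
        """
        m = len(spec.pam_iupac)
        margin = spec.protospacer_len + m
        lo = max(0, pos - margin)
        hi = min(len(self.seq), pos + len(block) + margin)
        text = "".join(self.seq[lo:pos]) + block + "".join(
            self.seq[pos + len(block) : hi]
        )
        block_lo, block_hi = pos - lo, pos - lo + len(block)
        for s, strand in _local_matches(text, spec):
            if s + m <= block_lo or s >= block_hi:
                continue  # entirely in flank: pre-existing background
            if (s + lo, strand) == intended:
                continue
            breakable = any(
                not (pos <= p < pos + len(block)) and not self._is_occupied(p)
                for p, _ in self._break_positions(spec, s + lo, strand)
            )
            if not breakable:
                return False
        return True

    def plant_guide_site(
        self,
        spec: PamSpec,
        gene_strand: str,
        desired_class: str,
        desired_unique: bool,
        position: int | None = None,
        feature_id: str | None = None,
        max_rolls: int = 100,
    ) -> PlantedSite:
        """Write a protospacer + concrete PAM so the resulting candidate has
        the desired targeting class and seed uniqueness.

        ``position`` is the forward-axis start of the planted block
        (protospacer+PAM on the + site strand, its reverse complement on
        -).  When omitted the position is drawn at random; a collision
        with a previous plant is re-rolled.
        """
        site_strand = _site_strand(gene_strand, desired_class)
        pam = concrete_pam(spec)
        block_len = spec.protospacer_len + len(pam)
        n = len(self.seq)
        if n < block_len:
            raise ValueError("insufficient space: contig shorter than guide block")
        for _ in range(max_rolls):
            pos = position
            if pos is None:
                pos = int(self.rng.integers(0, n - block_len + 1))
            elif pos < 0 or pos + block_len > n:
                raise ValueError(f"insufficient space at position {pos}")
            if self._collides(pos, pos + block_len):
                if position is not None:
                    raise ValueError(f"position {position} collides with a previous plant")
                continue
            proto = self._random_protospacer(spec.protospacer_len)
            if site_strand == "+":
                block = proto + pam
                proto_start, pam_start = pos, pos + spec.protospacer_len
            else:
                block = reverse_complement(proto + pam)
                pam_start, proto_start = pos, pos + len(pam)
            if not self._insertion_is_scrubbable(
                spec, pos, block, (pam_start, site_strand)
            ):
                continue  # incidental motif locked inside the block: re-roll
            self._write(pos, block)
            self.intended_pams.add((pam_start, site_strand))
            if self._in_protected(pos, pos + block_len):
                self.scrub(spec)  # clear junction-spawned occurrences
            entry = PlantedSite(
                system=spec.system_name,
                contig_id=self.contig_id,
                feature_id=feature_id,
                gene_strand=gene_strand,
                site_strand=site_strand,
                proto_start=proto_start,
                proto_end=proto_start + spec.protospacer_len,
                pam_start=pam_start,
                pam_end=pam_start + len(pam),
                targeting_sequence=proto,
                seed_sequence=proto[-spec.seed_len :],
                expected_class=desired_class,
                expected_unique=desired_unique,
            )
            if not desired_unique:
                entry.decoy_start = self._plant_decoy(spec, entry.seed_sequence, pam)
            self.ledger.append(entry)
            return entry
        raise ValueError("could not place guide site without collision")

    def _plant_decoy(self, spec: PamSpec, seed: str, pam: str,
                     max_rolls: int = 100) -> int:
        """Plant a second PAM-adjacent copy of *seed* elsewhere (+ strand),
        outside every protected zone so it never enters a design window."""
        block = seed + pam
        n = len(self.seq)
        margin = spec.protospacer_len + len(pam)
        for _ in range(max_rolls):
            pos = int(self.rng.integers(0, n - len(block) + 1))
            if self._collides(pos, pos + len(block)):
                continue
            if self._in_protected(pos - margin, pos + len(block) + margin):
                continue
            # incidental extra motifs around the decoy only raise the
            # seed's multiplicity further, which the expectation (>= 2)
            # already allows, so no cleanliness check is needed here
            self._write(pos, block)
            self.intended_pams.add((pos + len(seed), "+"))
            return pos
        raise ValueError("could not place decoy seed without collision")

    def add_tss(self, record: TssRecord, protect_for: PamSpec | None = None,
                upstream: int = -50, downstream: int = 100) -> None:
        self.tss_records.append(record)
        if protect_for is not None:
            p = record.tss_position
            if record.strand == "+":
                start, end = p - 1 + upstream, p - 1 + downstream
            else:
                start, end = p - downstream, p - upstream
            n = len(self.seq)
            self.protect_window(protect_for, max(0, start), min(n, end))

    def plant_for_tss(self, spec: PamSpec, tss: TssRecord, desired_class: str,
                      desired_unique: bool, offset: int) -> PlantedSite:
        """Plant a guide whose protospacer starts at transcript *offset*
        (offset 0 = the TSS base) relative to *tss*.

        The protospacer occupies transcript offsets [offset, offset +
        protospacer_len); with the default window both bounds must fall
        in [-50, 100) for the candidate to be designable.
        """
        p0 = tss.tss_position - 1
        m = len(concrete_pam(spec))
        site_strand = _site_strand(tss.strand, desired_class)
        if tss.strand == "+":
            proto_fwd_start = p0 + offset
        else:
            proto_fwd_start = p0 - offset - (spec.protospacer_len - 1)
        # the layout block starts at the PAM when the PAM sits left of the
        # protospacer on the forward axis (minus-strand sites)
        position = proto_fwd_start - m if site_strand == "-" else proto_fwd_start
        return self.plant_guide_site(
            spec, tss.strand, desired_class, desired_unique,
            position=position, feature_id=tss.feature_id,
        )

    def genome(self) -> Genome:
        return Genome(contigs={self.contig_id: "".join(self.seq)})


def plant_guide_site(
    genome: Genome,
    spec: PamSpec,
    gene_strand: str,
    desired_class: str,
    desired_unique: bool,
    position: int | None = None,
    seed: int | None = None,
) -> tuple[Genome, PlantedSite]:
    """One-shot planting into an existing single-contig genome."""
    planter = FixturePlanter(genome, np.random.default_rng(seed))
    entry = planter.plant_guide_site(
        spec, gene_strand, desired_class, desired_unique, position=position
    )
    return planter.genome(), entry


def random_planted_fixture(
    seed: int,
    n_genes: int = 6,
    spec: PamSpec | None = None,
    gc: float = 0.67,
    gene_spacing: int = 500,
    nonunique_every: int | None = None,
) -> tuple[Genome, list[TssRecord], list[PlantedSite]]:
    """In-memory fixture: one unique nontemplate guide planted per gene.

    Gene strands and in-window protospacer offsets are drawn from the
    seeded generator; every ``nonunique_every``-th gene (if set) gets a
    non-unique site instead.  Returns (genome, tss records, ledger).
    """
    spec = spec or BUILTIN_SYSTEMS["Sth3"]
    rng = np.random.default_rng(seed)
    length = 400 + n_genes * gene_spacing
    base = generate_genome(length, gc, rng=rng)
    planter = FixturePlanter(base, rng)
    tss_list = []
    for i in range(n_genes):
        p = 300 + i * gene_spacing
        strand = "+" if rng.integers(2) == 0 else "-"
        cds = p + 45 if strand == "+" else p - 45
        t = TssRecord(f"g{i + 1:03d}", planter.contig_id, p, strand, cds_start=cds)
        tss_list.append(t)
        planter.add_tss(t, protect_for=spec)
    planter.scrub(spec)
    for i, t in enumerate(tss_list):
        unique = not (nonunique_every and (i + 1) % nonunique_every == 0)
        offset = int(rng.integers(-50, 100 - spec.protospacer_len + 1))
        planter.plant_for_tss(spec, t, "nontemplate", unique, offset=offset)
    return planter.genome(), planter.tss_records, planter.ledger


def write_sam(path, genome: Genome, fragments: list[tuple[str, int, int]],
              read_len: int = 50) -> None:
    """Write properly-paired SAM records for the given fragment spans.

    Each (contig, start, end) span (0-based half-open) becomes one proper
    pair: mates of ``read_len`` bases anchored at the two fragment ends.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for cid in genome.contigs:
            fh.write(f"@SQ\tSN:{cid}\tLN:{genome.length(cid)}\n")
        recs = []
        for i, (cid, start, end) in enumerate(fragments):
            span = end - start
            r = min(read_len, span)
            if span <= 0 or end > genome.length(cid):
                raise ValueError(f"bad fragment span [{start}, {end}) on {cid!r}")
            qname = f"frag{i:06d}"
            seq1 = genome.fetch(cid, start, start + r)
            seq2 = genome.fetch(cid, end - r, end)
            qual = "I" * r
            recs.append((start, f"{qname}\t99\t{cid}\t{start + 1}\t60\t{r}M\t=\t"
                                f"{end - r + 1}\t{span}\t{seq1}\t{qual}"))
            recs.append((end - r, f"{qname}\t147\t{cid}\t{end - r + 1}\t60\t{r}M\t=\t"
                                  f"{start + 1}\t{-span}\t{seq2}\t{qual}"))
        for _, line in sorted(recs, key=lambda t: t[0]):
            fh.write(line + "\n")


@dataclass
class FixtureBundle:
    """Paths and expectations of one generated fixture set."""

    profile: str
    seed: int
    out_dir: Path
    genome_path: Path
    tss_path: Path
    ledger_path: Path
    genes_path: Path | None = None
    sam_paths: dict[str, Path] | None = None
    expectations: dict | None = None


def _genes_table_lines(genes: list[tuple[str, str, int, int]]) -> str:
    lines = ["feature_id\tcontig\tstart\tend"]
    lines += [f"{fid}\t{cid}\t{s}\t{e}" for fid, cid, s, e in genes]
    return "\n".join(lines) + "\n"


def make_fixture_bundle(profile: str, seed: int, out_dir) -> FixtureBundle:
    """Emit a named, self-consistent fixture set to *out_dir*.

    Profiles:

    * ``minimal`` — 1 contig, 2 genes, 1 planted unique nontemplate guide;
    * ``coverage-demo`` — 4 TSS-bearing genes, unique nontemplate guides
      planted for 3 (gene targetability 75.0%), plus one non-unique site;
    * ``rnaseq-demo`` — 10 genes and paired-end SAM files for two
      conditions with a planted 4-fold induction of one gene.

    Re-running with the same profile and seed is byte-identical.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sth3 = BUILTIN_SYSTEMS["Sth3"]

    if profile == "minimal":
        base = generate_genome(4000, 0.67, rng=rng)
        planter = FixturePlanter(base, rng)
        tss_a = TssRecord("geneA", planter.contig_id, 1001, "+", cds_start=1041)
        tss_b = TssRecord("geneB", planter.contig_id, 3001, "-", cds_start=2961)
        planter.add_tss(tss_a, protect_for=sth3)
        planter.add_tss(tss_b, protect_for=sth3)
        planter.scrub(sth3)
        planter.plant_for_tss(sth3, tss_a, "nontemplate", True, offset=10)
        genes = None
        sams = None
        expectations = {"n_planted": 1, "targetable_genes": ["geneA"],
                        "pct_targetable": 50.0}
    elif profile == "coverage-demo":
        base = generate_genome(10000, 0.67, rng=rng)
        planter = FixturePlanter(base, rng)
        layout = [("gene1", 1001, "+"), ("gene2", 3001, "-"),
                  ("gene3", 5001, "+"), ("gene4", 7001, "-")]
        tss_by_gene = {}
        for fid, p, strand in layout:
            cds = p + 60 if strand == "+" else p - 60
            t = TssRecord(fid, planter.contig_id, p, strand,
                          operon_id=f"op_{fid}", cds_start=cds)
            tss_by_gene[fid] = t
            planter.add_tss(t, protect_for=sth3)
        planter.scrub(sth3)
        # unique nontemplate guides for genes 1-3; gene4 gets a non-unique site
        for fid, p, strand in layout[:3]:
            planter.plant_for_tss(sth3, tss_by_gene[fid], "nontemplate", True,
                                  offset=10)
        planter.plant_for_tss(sth3, tss_by_gene["gene4"], "nontemplate", False,
                              offset=10)
        genes = None
        sams = None
        expectations = {"n_planted": 4,
                        "targetable_genes": ["gene1", "gene2", "gene3"],
                        "pct_targetable": 75.0}
    else:  # rnaseq-demo
        base = generate_genome(8000, 0.67, rng=rng)
        planter = FixturePlanter(base, rng)
        genes = []
        for i in range(10):
            fid = f"gene{i + 1:02d}"
            start1 = 200 + i * 760 + 1  # 1-based, 400 bp genes spaced 760 apart
            genes.append((fid, planter.contig_id, start1, start1 + 399))
            planter.add_tss(TssRecord(fid, planter.contig_id, max(start1 - 30, 1), "+",
                                      cds_start=start1))
        induced = "gene05"
        frag_span = 200
        conditions: dict[str, list] = {"a": [], "b": []}
        for fid, cid, s1, e1 in genes:
            n_b = 20
            n_a = 80 if fid == induced else 20
            s0 = s1 - 1
            for cond, n_frags in (("a", n_a), ("b", n_b)):
                for j in range(n_frags):
                    off = int(rng.integers(0, 400 - frag_span + 1))
                    conditions[cond].append((cid, s0 + off, s0 + off + frag_span))
        # balance library sizes with intergenic background in condition b,
        # so per-gene RPKM ratios reflect the planted masses directly
        cid = planter.contig_id
        for j in range(60):
            gap_start = 200 + (j % 9) * 760 + 400  # 360-bp gap after each gene
            off = int(rng.integers(0, 360 - frag_span + 1))
            conditions["b"].append((cid, gap_start + off, gap_start + off + frag_span))
        sams = conditions
        expectations = {"induced_gene": induced, "fold_change": 4.0,
                        "log2_fold_change": 2.0,
                        "fragments_per_condition": {"a": 10 * 20 + 60,
                                                    "b": 10 * 20 + 60}}

    genome = planter.genome()
    genome_path = out / "genome.fasta"
    tss_path = out / "tss.tsv"
    ledger_path = out / "ledger.json"
    write_fasta(genome, genome_path)
    write_tss_table(planter.tss_records, tss_path)

    bundle = FixtureBundle(
        profile=profile, seed=seed, out_dir=out,
        genome_path=genome_path, tss_path=tss_path, ledger_path=ledger_path,
        expectations=expectations,
    )
    if genes is not None:
        bundle.genes_path = out / "genes.tsv"
        bundle.genes_path.write_text(_genes_table_lines(genes))
    if sams is not None:
        bundle.sam_paths = {}
        for cond, frags in sams.items():
            p = out / f"reads_{cond}.sam"
            write_sam(p, genome, frags)
            bundle.sam_paths[cond] = p

    ledger = {
        "profile": profile,
        "seed": seed,
        "contig": planter.contig_id,
        "planted_sites": [asdict(e) for e in planter.ledger],
        "expectations": expectations,
    }
    ledger_path.write_text(json.dumps(ledger, indent=2, sort_keys=True) + "\n")
    (out / "README.txt").write_text(
        f"Synthetic fixture bundle, profile={profile!r}, seed={seed}.\n"
        "All sites listed in ledger.json were written verbatim into genome.fasta\n"
        "and are verifiable by direct string inspection; 'expectations' states\n"
        "what the design/quantification pipeline should recover.\n"
    )
    return bundle
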