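# Methods

## The design problem

CRISPRi silences a gene by parking catalytically dead Cas9 (dCas9) on
the DNA near the start of the transcript, guided by a single guide RNA
(sgRNA) whose 20-nt spacer matches a genomic protospacer next to a
protospacer-adjacent motif (PAM). Silencing is efficient when the sgRNA
base-pairs with the nontemplate (coding) strand in the promoter-proximal
region; because the 12 bases of the spacer adjacent to the PAM (the
seed) are sufficient for dCas9 recruitment, a seed that recurs next to
another PAM elsewhere in the genome is an off-target liability. The
toolkit turns these observations into three filters — PAM adjacency,
window/strand placement, seed uniqueness — plus accounting, construct
assembly, and knockdown quantification.

## Coordinate and strand conventions

Internally every interval is 0-based half-open on the forward axis of a
contig; user-facing TSV is 1-based inclusive and BED output is standard
0-based half-open. Transcript offsets are oriented along transcription
with offset 0 at the TSS base; the default window is [−50, +100)
(length 150). A guide is classified *nontemplate* exactly when its
protospacer strand differs from the annotated gene strand: the sgRNA
sequence equals the protospacer, so it base-pairs with the strand whose
sequence matches the mRNA. `tss_offset` is the transcript offset of the
protospacer base nearest the TSS (0 if the protospacer covers the TSS);
it is the primary sort key so nearest guides list first, with ties
broken by forward-axis start and then + before −.

## PAM scanning

Motifs are IUPAC-degenerate, matched by compiled regular expressions
with a lookahead so overlapping occurrences all count, once per
(position, strand). Minus-strand occurrences are found by matching the
motif's reverse complement against the forward sequence. A genome `N`
matches no motif letter, including IUPAC `N`: an ambiguous base cannot
be claimed as a determinate guide or PAM base. Both strands are scanned
and counted by default; single-strand scans are available for
sensitivity analysis. Contigs are linear by default; a contig declared
circular is scanned across its origin and protospacer extraction wraps.
PAM geometry is fixed to type IIA (PAM 3′ of the protospacer). The
*S. pasteurianus* system is scanned with its consensus `NNGTGA` only —
relaxed PAM preferences are expressed by configuring additional motifs,
never by fuzzy matching.

## Seed-uniqueness filter

For each system, an index maps every N-free `seed_len`-mer lying
immediately 5′ of a PAM occurrence (either strand) to its genome-wide
count. Indexing requires only the seed-length window, not a full
protospacer: a PAM too close to a contig edge for 20 bases but with 12
N-free bases still contributes a binding-competent off-target locus. A
candidate is unique iff its seed's count is exactly 1 — the candidate's
own locus is included, which makes "found only once in the genome" and
"no perfect match elsewhere" equivalent. Seeds are compared within one
system only, since a seed next to a different system's PAM is invisible
to that Cas9.

## Window selection and the design table

For each TSS record the window offsets are oriented by gene strand,
mapped to the forward axis and clipped to the contig. The full
protospacer must lie inside the window; the PAM may extend past either
edge (a `require_pam_in_window` toggle tightens this). Genes with
several TSS records are designed independently per TSS and aggregated
only in the targetability report. Candidates overlapping the annotated
start codon are flagged (`beyond_cds_start`) but never filtered — such
guides are reported because their placement is valid, while their
efficacy is annotation, not a claim. The genome-wide design table is
fully deterministic: rerunning on identical inputs is byte-identical.

## Targetability accounting

A gene (or operon, when operon ids are annotated) counts as targetable
under a set of systems if at least one of its TSS records has at least
one unique nontemplate candidate from any system in the set; the
denominator is units carrying at least one TSS record. Percentages are
rounded half-up to one decimal. Union rows let one read off the gain
from combining systems; adding a system can never decrease the count.

## Construct assembly

A construct is the 20-nt targeting sequence followed by the system's
crRNA direct repeat + tracrRNA scaffold, in DNA alphabet for cloning;
an RNA display form transliterates T→U. Scaffolds are configuration
inputs: the repeat/tracrRNA sequences belong to the expression plasmids
of each system and shipping invented defaults would fabricate biology.

## Expression quantification

Each properly paired fragment contributes total mass 1, spread as 1/N
over the N positions from the 5′ end of the first mate to the 3′ end of
the second (coverage is unstranded; unpaired mapped reads contribute
1/read-length over the read span; unmapped, secondary and supplementary
records are skipped and tallied). Per-gene mass is the coverage sum over
the annotated interval. RPKM = mass / (gene length in kb) / (fragments
in millions). The pseudocount that keeps log ratios finite is ambiguous
in placement and magnitude, so two modes are provided and recorded in
output headers: the default `per-gene` mode adds 1 fragment-equivalent
of mass per gene (a length-independent floor); the literal
`per-position` mode adds a constant (default 10⁻³) at every position of
the gene interval, making the floor scale with length. Knockdown is the
per-gene log₂ RPKM ratio of experimental to control condition.
Fragments straddling a gene boundary contribute only the mass of the
positions inside the interval.

## Synthetic fixtures

The generator emulates the *shape* of the target problem — a GC-rich
(default 67% GC) bacterial genome with TSS-annotated genes and
PAM-adjacent protospacers planted at known coordinates — so every stage
is testable offline against a planting ledger. Randomness is
`numpy.random.default_rng` (PCG64) throughout, so a seed reproduces
byte-identical files on any platform. Planted PAMs use the
least-degenerate concrete instantiation of the motif (N→A, e.g. `AGGAG`
for `NGGNG`).

Exact planted-set recovery requires that design windows contain no
candidates besides the planted ones, which a 67% GC background would
violate constantly (that density is the point of the `NGGNG` motif). The
planter therefore scrubs protected window neighborhoods of background
motif occurrences by deterministic single-base edits before planting,
re-rolls any protospacer whose insertion would lock an incidental motif
inside the planted block, and scrubs junction-spawned occurrences
afterwards. Non-unique sites are made by planting a second PAM-adjacent
copy of the seed outside all windows. The RNA-seq profile plants
per-gene fragment counts (20 per gene, 80 for the induced gene, 4-fold)
and balances library sizes with intergenic background fragments so the
recovered log₂ ratio is log₂(81/21) ≈ 1.95 under the default per-gene
pseudocount — within 0.06 of the planted 2.0.

What fixtures do **not** emulate: real promoter/operon structure,
sequence composition beyond i.i.d. base frequencies, sequencing error,
fragment-length distributions, or biological expression variance.
Passing tests therefore demonstrate the correctness of the scanning,
filtering, accounting and quantification rules, not performance claims
about any particular organism's annotation.

## Problem sizes and numerical choices

Property suites run on seeded random genomes of 0.2–5 kb (hundreds of
replicates) against brute-force oracles, and fixture profiles of 4–10 kb
with 2–10 genes; the acceptance script measures PAM densities on a
200-kb synthetic genome and targetability on a 40-gene fixture. These
sizes give exact, deterministic expectations while keeping the whole
suite fast; the scanning path itself is linear in genome length and
handles megabase genomes directly. Coverage mass conservation is
asserted to 10⁻⁶ relative; percentages use decimal half-up rounding to
one decimal; RPKM uses float64 throughout.

## Known limitations

- No guide-efficacy scoring or ranking beyond distance to the TSS; the
  method's filters are categorical.
- No mismatch-tolerant off-target search: uniqueness is exact seed
  identity next to a same-system PAM, by design.
- TSS annotation is consumed as given; no promoter inference.
- Reproducing published reference-genome figures requires the reference
  FASTA and TSS table as local inputs; whether the original counts used
  one or both strands, or wrapped the circular origin, is not recorded
  anywhere authoritative, so scan strand mode and topology are explicit
  toggles recorded in output headers.
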