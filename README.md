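# crispridesign

A guide-design toolkit for bacterial CRISPR interference (CRISPRi).
Given a genome FASTA and a transcription-start-site (TSS) annotation, it
enumerates every occurrence of a Cas9 system's protospacer-adjacent
motif (PAM) on both strands, extracts the 20-base protospacers ending 5′
of each PAM, selects candidates whose sgRNA would base-pair with the
**nontemplate strand** inside a window from −50 to +100 around each TSS,
and discards guides whose 12-base PAM-adjacent **seed** occurs more than
once in the genome next to a PAM of the same system — the seed match
alone suffices to recruit dCas9, so a recurring seed risks off-target
silencing. It also reports genome-wide targetability (what fraction of
TSS-bearing genes/operons has at least one unique nontemplate guide),
assembles full sgRNA construct sequences (spacer + crRNA repeat +
tracrRNA scaffold), and quantifies RNA-seq knockdown via fractional
fragment coverage and RPKM.

Intended users: bacterial geneticists building CRISPRi knockdown
libraries, particularly for GC-rich organisms such as *Caulobacter
crescentus* where the *S. thermophilus* CRISPR3 PAM `NGGNG` and the
*S. pasteurianus* consensus PAM `NNGTGA` are the built-in systems
(`Sth3`, `Spa`). Any type IIA system can be added through a YAML config.

## Core rules

- **PAM scan**: every window matching the IUPAC motif on either strand
  is a site; overlaps all count; a genome `N` matches no motif letter.
- **Guide geometry**: the targeting sequence is the `protospacer_len`
  (default 20) bases ending immediately 5′ of the PAM, read 5′→3′ on the
  PAM's strand; the seed is its `seed_len` (default 12) PAM-adjacent
  suffix.
- **Strand rule**: an sgRNA is *nontemplate-targeting* when its
  protospacer lies on the genomic strand opposite the annotated gene
  strand (the sgRNA then base-pairs with the nontemplate/coding strand).
- **Window**: the whole protospacer must lie within transcript offsets
  [−50, +100) of the TSS (offset 0 = the TSS base).
- **Uniqueness**: a guide is kept iff its seed occurs exactly once
  genome-wide immediately 5′-adjacent to a PAM of the same system,
  counting both strands and the guide's own locus.
- **Expression**: each properly paired fragment adds 1/N to each of the
  N positions it spans; per-gene mass is pseudocounted and normalized to
  RPKM; knockdown is the log₂ RPKM ratio between conditions.

## Worked example

Everything below runs offline on a generated fixture: a 10-kb, 67% GC
synthetic genome with four TSS-annotated genes, unique nontemplate
guides planted for three of them and a deliberately non-unique site for
the fourth.

```sh
crispri fixture --profile coverage-demo --seed 7 --out-dir fx
crispri design  --genome fx/genome.fasta --tss fx/tss.tsv --system Sth3 --out-prefix guides
crispri stats   --design guides.tsv --genome fx/genome.fasta --tss fx/tss.tsv --unit gene --out stats.tsv
```

`stats.tsv` (comment headers omitted):

```
unit	systems	n_units_with_tss	n_units_targetable	pct_targetable
gene	Sth3	4	3	75.0
```

Four genes carry a TSS; three have at least one unique nontemplate-strand
guide, so 75.0% of genes are targetable — the fourth gene's only
candidate appears in `guides.tsv` with `seed_multiplicity 2` and
`unique False`, exactly the planted off-target duplication. Each row of
`guides.tsv` carries the guide's 1-based coordinates, strand, transcript
offset from the TSS, targeting and seed sequences, and whether any base
falls at or beyond the annotated start codon.

On a real genome the same two commands run against the organism's FASTA
and TSS table; `crispri scan` prints genome-wide PAM totals, `crispri
construct` appends a configured scaffold to produce clonable sgRNA
sequences, and `crispri quant` turns paired-end SAM alignments into an
RPKM/log₂-ratio table.

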