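"""RNA-seq quantification: fractional fragment coverage, RPKM, log2 ratios.

Each properly mapped fragment contributes total mass 1, spread uniformly
as 1/N over the N genomic positions from the 5' end of the first mate to
the 3' end of the second.  Per-gene mass is summed over the annotated
gene interval, pseudocounted, and normalized to RPKM (reads per kilobase
per million fragments).  Expression changes are log2 ratios of RPKM
between conditions.

Coverage is unstranded.  Alignment is consumed, never performed: SAM is
the interface.  Unmapped (0x4), secondary (0x100) and supplementary
(0x800) records are skipped.

Pseudocount modes (the floor that keeps ratios finite):

* ``per-gene`` (default): adds a constant mass of ``pseudocount``
  fragment-equivalents to every gene, a length-independent floor;
* ``per-position``: adds ``pseudocount`` at every position of the gene
  interval, so the floor scales with gene length;
* ``off``: no floor (ratios may be undefined for silent genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import Genome

PSEUDOCOUNT_MODES = ("per-gene", "per-position", "off")


@dataclass
class FragmentCoverage:
    """Per-contig fractional coverage vectors plus bookkeeping tallies."""

    vectors: dict[str, np.ndarray]
    total_fragments: int = 0
    n_skipped: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def mass(self) -> float:
        return float(sum(v.sum() for v in self.vectors.values()))

    def _skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


def fragment_coverage(sam_path, genome: Genome) -> FragmentCoverage:
    """Accumulate 1/N fragment coverage from a SAM file.

    Proper pairs contribute once per fragment (counted at the leftmost
    mate, template length > 0) over the full template span.  Unpaired
    mapped reads contribute 1/read-length over the read span.  Records
    with a nonpositive or contig-exceeding span are tallied and skipped,
    never fatal.
    """
    cov = FragmentCoverage(
        vectors={cid: np.zeros(genome.length(cid)) for cid in genome.contigs}
    )
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                cov._skip("not_primary_mapped")
                continue
            cid = read.reference_name
            if cid not in cov.vectors:
                cov._skip("unknown_contig")
                continue
            vec = cov.vectors[cid]
            if read.is_paired and read.is_proper_pair:
                tlen = read.template_length
                if tlen <= 0:
                    continue  # fragment is counted once, at the leftmost mate
                start = read.reference_start
                end = start + tlen
                if end > len(vec):
                    cov._skip("span_exceeds_contig")
                    continue
                vec[start:end] += 1.0 / tlen
                cov.total_fragments += 1
            else:
                start, end = read.reference_start, read.reference_end
                if end is None or end <= start or end > len(vec):
                    cov._skip("bad_span")
                    continue
                vec[start:end] += 1.0 / (end - start)
                cov.total_fragments += 1
    return cov


def gene_rpkm(
    coverage: FragmentCoverage,
    genes: pd.DataFrame,
    pseudocount_mode: str = "per-gene",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene fragment mass and RPKM.

    ``genes`` needs columns feature_id, contig, start, end (1-based
    inclusive).  RPKM = mass / (length in kb) / (library in millions),
    where library size is the number of fragments used for coverage.
    """
    if pseudocount_mode not in PSEUDOCOUNT_MODES:
        raise ValueError(
            f"pseudocount_mode must be one of {PSEUDOCOUNT_MODES}, got {pseudocount_mode!r}"
        )
    if coverage.total_fragments == 0:
        raise ValueError("zero fragments in library: RPKM normalization undefined")
    millions = coverage.total_fragments / 1e6
    rows = []
    for rec in genes.itertuples(index=False):
        vec = coverage.vectors[rec.contig]
        start0, end0 = int(rec.start) - 1, int(rec.end)
        if not (0 <= start0 < end0 <= len(vec)):
            raise ValueError(
                f"gene {rec.feature_id!r} interval [{rec.start}, {rec.end}] "
                f"outside contig {rec.contig!r}"
            )
        length_bp = end0 - start0
        mass = float(vec[start0:end0].sum())
        if pseudocount_mode == "per-gene":
            mass += pseudocount
        elif pseudocount_mode == "per-position":
            mass += pseudocount * length_bp
        rpkm = mass / (length_bp / 1000.0) / millions
        rows.append({
            "feature_id": rec.feature_id,
            "contig": rec.contig,
            "start": int(rec.start),
            "end": int(rec.end),
            "length_bp": length_bp,
            "fragment_mass": mass,
            "rpkm": rpkm,
        })
    return pd.DataFrame(rows)


def log2_fold_change(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene log2(RPKM_a / RPKM_b); gene sets must match exactly."""
    genes_a = set(table_a["feature_id"])
    genes_b = set(table_b["feature_id"])
    if genes_a != genes_b:
        raise ValueError(
            f"gene sets differ: only in a = {sorted(genes_a - genes_b)}, "
            f"only in b = {sorted(genes_b - genes_a)}"
        )
    a = table_a.set_index("feature_id")["rpkm"]
    b = table_b.set_index("feature_id")["rpkm"]
    lfc = np.log2(a / b.reindex(a.index))
    return pd.DataFrame({
        "feature_id": a.index,
        "rpkm_a": a.values,
        "rpkm_b": b.reindex(a.index).values,
        "log2_ratio": lfc.values,
    })
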