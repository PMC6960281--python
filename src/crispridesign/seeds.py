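"""Seed-uniqueness off-target filtering.

The 12 bases of a spacer adjacent to the PAM (the "seed") are sufficient
for dCas9 recruitment, so a guide whose seed recurs next to another PAM
elsewhere in the genome risks off-target silencing.  The filter keeps a
guide only if its seed occurs exactly once in the whole genome
immediately 5'-adjacent to a PAM of the same system (both strands
counted; the candidate's own locus counts, so unique <=> count == 1).

Indexing adjacency requires only ``seed_len`` bases 5' of a PAM, not a
full protospacer: a PAM too close to a contig edge for a 20-base spacer
but with 12 N-free upstream bases still contributes an off-target
occurrence, because binding needs only the seed match.  Seeds containing
``N`` are excluded from both the index and candidacy.  Seeds are compared
within one Cas9 system only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome import Genome
from .pam import PamSpec, Protospacer, extract_upstream, scan_pams


@dataclass
class SeedIndex:
    """Genome-wide multiplicity of PAM-adjacent seed sequences for one system."""

    system_name: str
    seed_len: int
    multiplicity: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.multiplicity)


def build_seed_index(genome: Genome, spec: PamSpec) -> SeedIndex:
    """Count every N-free seed window 5'-adjacent to a PAM, both strands.

    Deterministic and independent of scan order (it is a pure tally).
    """
    index = SeedIndex(system_name=spec.system_name, seed_len=spec.seed_len)
    for site in scan_pams(genome, spec, "both"):
        got = extract_upstream(genome, site, spec.seed_len)
        if got is None:
            continue
        seed = got[2]
        if "N" in seed:
            continue
        index.multiplicity[seed] += 1
    return index


def seed_multiplicity(index: SeedIndex, candidate: Protospacer) -> int:
    """Genome-wide PAM-adjacent count of the candidate's seed (>= 1).

    A zero count signals a genome/system mismatch between the candidate
    and the index and is raised as an error rather than returned.
    """
    count = index.multiplicity.get(candidate.seed_sequence, 0)
    if count < 1:
        raise ValueError(
            f"seed {candidate.seed_sequence!r} absent from the {index.system_name} "
            "index: candidate and index were built from different genomes or systems"
        )
    return count


def filter_unique(
    candidates: list[Protospacer], index: SeedIndex
) -> tuple[list[Protospacer], list[tuple[Protospacer, int]]]:
    """Split candidates into (unique, rejected-with-multiplicity), order preserved."""
    kept: list[Protospacer] = []
    rejected: list[tuple[Protospacer, int]] = []
    for cand in candidates:
        count = seed_multiplicity(index, cand)
        if count == 1:
            kept.append(cand)
        else:
            rejected.append((cand, count))
    return kept, rejected
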