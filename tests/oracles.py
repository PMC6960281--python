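"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (naive sliding windows,
direct string slicing) and deliberately shares no code with the package.
"""

from __future__ import annotations

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _matches_at(seq: str, i: int, motif: str) -> bool:
    return all(seq[i + j] in IUPAC_SETS[motif[j]] for j in range(len(motif)))


def brute_force_pam_scan(seq: str, motif: str) -> list[tuple[int, str]]:
    """All (forward-axis start, strand) motif occurrences, both strands.

    A minus-strand occurrence at reverse-complement index i maps to the
    forward interval [L - i - m, L - i).
    """
    L, m = len(seq), len(motif)
    rc = revcomp(seq)
    sites = []
    for i in range(L - m + 1):
        if _matches_at(seq, i, motif):
            sites.append((i, "+"))
    for i in range(L - m + 1):
        if _matches_at(rc, i, motif):
            sites.append((L - i - m, "-"))
    return sorted(sites)


def brute_force_seed_counts(seq: str, motif: str, seed_len: int) -> dict[str, int]:
    """Multiplicity of each N-free seed immediately 5' of a PAM occurrence."""
    counts: dict[str, int] = {}
    m = len(motif)
    for start, strand in brute_force_pam_scan(seq, motif):
        if strand == "+":
            lo, hi = start - seed_len, start
            if lo < 0:
                continue
            seed = seq[lo:hi]
        else:
            lo, hi = start + m, start + m + seed_len
            if hi > len(seq):
                continue
            seed = revcomp(seq[lo:hi])
        if "N" in seed:
            continue
        counts[seed] = counts.get(seed, 0) + 1
    return counts
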