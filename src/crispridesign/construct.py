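"""sgRNA construct assembly.

A single guide RNA is a 20-nt targeting region followed by the Cas9
system's crRNA direct repeat and tracrRNA (which carries the dCas9
handle and a transcriptional terminator).  This module concatenates a
chosen targeting sequence with a system's scaffold, in DNA alphabet
(cloning-oriented); transcription to RNA is display-only.

Scaffold sequences are configuration inputs, never shipped constants:
the repeat/tracrRNA sequences live on the reference expression plasmids.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pam import PamSpec


@dataclass(frozen=True)
class SgRnaConstruct:
    """A full sgRNA expression sequence: targeting region + scaffold, 5'->3'."""

    system_name: str
    targeting_sequence: str
    full_sequence: str
    notes: str = ""

    def as_rna(self) -> str:
        """Display transliteration of the construct to the RNA alphabet."""
        return self.full_sequence.replace("T", "U")


def assemble_construct(targeting: str, spec: PamSpec, notes: str = "") -> SgRnaConstruct:
    """Concatenate targeting sequence and scaffold for one system.

    The targeting sequence must be A/C/G/T only and exactly
    ``spec.protospacer_len`` long; the spec must carry a scaffold.
    """
    targeting = targeting.upper()
    if spec.scaffold is None:
        raise ValueError(
            f"system {spec.system_name!r} has no scaffold configured; "
            "supply the crRNA repeat + tracrRNA sequence in the system config"
        )
    if len(targeting) != spec.protospacer_len:
        raise ValueError(
            f"targeting sequence length {len(targeting)} != protospacer_len "
            f"{spec.protospacer_len}"
        )
    bad = set(targeting) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous base(s) {sorted(bad)} in targeting sequence")
    return SgRnaConstruct(
        system_name=spec.system_name,
        targeting_sequence=targeting,
        full_sequence=targeting + spec.scaffold.upper(),
        notes=notes,
    )
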