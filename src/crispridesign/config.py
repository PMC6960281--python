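"""System configuration loading (YAML).

A config file maps system names to PAM/guide parameters, e.g.::

    systems:
      Sth3:
        pam: NGGNG
        protospacer_len: 20
        seed_len: 12
        scaffold: GTTTTAGAGC...   # crRNA repeat + tracrRNA, optional
      Spy:
        pam: NGG

Built-in systems (Sth3, Spa) may be used without a config; a config
entry with the same name overrides the built-in.
"""

from __future__ import annotations

import yaml

from .pam import BUILTIN_SYSTEMS, PamSpec


def load_systems(path=None) -> dict[str, PamSpec]:
    """Merge built-in systems with an optional YAML config."""
    systems = dict(BUILTIN_SYSTEMS)
    if path is None:
        return systems
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for name, entry in (data.get("systems") or {}).items():
        if "pam" not in entry:
            raise ValueError(f"system {name!r}: config entry missing 'pam'")
        systems[name] = PamSpec(
            system_name=name,
            pam_iupac=str(entry["pam"]),
            protospacer_len=int(entry.get("protospacer_len", 20)),
            seed_len=int(entry.get("seed_len", 12)),
            scaffold=entry.get("scaffold"),
        )
    return systems


def get_system(systems: dict[str, PamSpec], name: str) -> PamSpec:
    if name not in systems:
        raise ValueError(
            f"unknown system {name!r}; known: {sorted(systems)} "
            "(add it to the YAML config)"
        )
    return systems[name]
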