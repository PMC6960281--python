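"""Genome-wide targetability accounting.

A gene (or operon) counts as *targetable* under a set of Cas9 systems
when at least one of its annotated TSS records has at least one unique
nontemplate-strand guide candidate from any system in the set.  The
denominator is the number of genes/operons carrying at least one TSS
record.  Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome import TssRecord


def _percent(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return 0.0
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class TargetabilityReport:
    """Per-system and system-union coverage statistics."""

    unit: str  # gene | operon
    rows: pd.DataFrame  # columns: systems, n_units_with_tss, n_units_targetable, pct_targetable
    provenance: dict


def _unit_of(tss: TssRecord, unit: str) -> str | None:
    return tss.feature_id if unit == "gene" else tss.operon_id


def summarize_targetability(
    design_table: pd.DataFrame,
    tss_records: list[TssRecord],
    unit: str = "gene",
    system_sets: list[tuple[str, ...]] | None = None,
    provenance: dict | None = None,
) -> TargetabilityReport:
    """Tabulate how many genes/operons have >= 1 unique nontemplate guide.

    ``system_sets`` lists the subsets to report; default is each system in
    the design table alone plus their full union.  The design table must
    carry ``unique`` and ``targeting_class`` columns (as produced by
    ``design_genome_wide``).
    """
    if unit not in ("gene", "operon"):
        raise ValueError(f"unit must be gene|operon, got {unit!r}")
    units_with_tss = {u for t in tss_records if (u := _unit_of(t, unit)) is not None}
    if unit == "operon" and not units_with_tss:
        raise ValueError("unit is operon but no operon ids are present")
    tss_to_unit = {
        (t.feature_id, t.tss_position, t.strand): _unit_of(t, unit)
        for t in tss_records
    }

    if system_sets is None:
        systems = sorted(design_table["system"].unique()) if len(design_table) else []
        system_sets = [(s,) for s in systems]
        if len(systems) > 1:
            system_sets.append(tuple(systems))

    usable = design_table
    if len(usable):
        usable = usable[
            (usable["targeting_class"] == "nontemplate") & (usable["unique"])
        ]

    rows = []
    denom = len(units_with_tss)
    for subset in system_sets:
        targetable: set[str] = set()
        if len(usable):
            sub = usable[usable["system"].isin(subset)]
            for fid, pos, strand in zip(
                sub["feature_id"], sub["tss_position"], sub["gene_strand"]
            ):
                u = tss_to_unit.get((fid, pos, strand))
                if u is not None:
                    targetable.add(u)
        targetable &= units_with_tss
        rows.append({
            "systems": "+".join(subset),
            "n_units_with_tss": denom,
            "n_units_targetable": len(targetable),
            "pct_targetable": _percent(len(targetable), denom),
        })
    return TargetabilityReport(
        unit=unit,
        rows=pd.DataFrame(
            rows,
            columns=[
                "systems", "n_units_with_tss", "n_units_targetable", "pct_targetable",
            ],
        ),
        provenance=dict(provenance or {}),
    )


def write_report(report: TargetabilityReport, path) -> None:
    """Serialize a report as TSV with a deterministic provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# unit: {report.unit}\n")
        for key in sorted(report.provenance):
            fh.write(f"# {key}: {report.provenance[key]}\n")
        report.rows.to_csv(fh, sep="\t", index=False, float_format="%.1f")
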