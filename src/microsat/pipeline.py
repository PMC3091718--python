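"""End-to-end orchestration: scan -> stats -> e-PCR -> polymorphism.

The functions here glue the per-module operations into the runs a user
would launch from the command line, and are also what the synthetic-study
round-trip tests drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .epcr import (
    BindingRules,
    PrimerPair,
    SpecificityResult,
    SpecificityStatus,
    run_epcr,
)
from .polymorphism import (
    CompoundKind,
    LocusComparison,
    PolymorphismClass,
    compound_repeat_units,
)
from .scan import ScanConfig, SSRLocus, scan_fasta
from .simulate import Fixture
from .stats import FrequencyTable, summarize_by_type

__all__ = [
    "scan_assembly",
    "comparison_from_results",
    "compare_runs",
    "fixture_primer_pairs",
    "analyze_fixture",
    "FixtureAnalysis",
]


def scan_assembly(
    fasta: str | Path, config: ScanConfig | None = None, label: str | None = None
) -> tuple[list[SSRLocus], int, FrequencyTable]:
    """Scan a FASTA assembly and summarize it: (loci, total_bp, table)."""
    cfg = config or ScanConfig()
    loci: list[SSRLocus] = []
    total_bp = 0
    for stats, record_loci in scan_fasta(fasta, cfg):
        total_bp += stats.length
        loci.extend(record_loci)
    table = summarize_by_type(loci, max(total_bp, 1), label=label or str(fasta))
    return loci, total_bp, table


def _metadata_from_amplicon(
    result: SpecificityResult, max_gap: int = 100
) -> dict:
    """Repeat metadata of the reference-side amplicon's flanked SSRs."""
    amp = result.amplicon
    if amp is None or not amp.flanked_ssrs:
        return {}
    members = list(amp.flanked_ssrs)
    periods = {l.period for l in members}
    canon = {l.canonical_motif for l in members}
    if len(members) == 1:
        kind = CompoundKind.SIMPLE
    elif len(canon) == 1 and len(periods) == 1:
        kind = CompoundKind.HOMOGENEOUS
    else:
        kind = CompoundKind.HETEROGENEOUS
    units = None
    if kind is CompoundKind.SIMPLE:
        units = members[0].repeat_units
    elif kind is CompoundKind.HOMOGENEOUS:
        units = compound_repeat_units([(l.motif, l.repeat_units) for l in members])
    return {
        "repeat_period": members[0].period if len(periods) == 1 else None,
        "canonical_motif": members[0].canonical_motif if len(canon) == 1 else None,
        "repeat_units_ref": units,
        "repeat_length_ref": sum(l.length for l in members),
        "compound": kind,
    }


def comparison_from_results(
    marker_id: str,
    ref: SpecificityResult,
    alt: SpecificityResult,
) -> LocusComparison:
    """One marker's comparison; non-specific sides become missing sizes."""
    size_ref = ref.amplicon.length if ref.status is SpecificityStatus.SPECIFIC else None
    size_alt = alt.amplicon.length if alt.status is SpecificityStatus.SPECIFIC else None
    meta = _metadata_from_amplicon(ref)
    return LocusComparison(marker_id=marker_id, size_ref=size_ref,
                           size_alt=size_alt, **meta)


def compare_runs(
    ref_results: Mapping[str, SpecificityResult],
    alt_results: Mapping[str, SpecificityResult],
) -> list[LocusComparison]:
    """Pair up two e-PCR runs marker by marker (union of marker ids)."""
    out = []
    for marker_id in sorted(set(ref_results) | set(alt_results)):
        ref = ref_results.get(marker_id)
        alt = alt_results.get(marker_id)
        if ref is None or alt is None:
            missing = SpecificityResult(marker_id, SpecificityStatus.NO_AMPLIFICATION)
            ref = ref or missing
            alt = alt or missing
        out.append(comparison_from_results(marker_id, ref, alt))
    return out


def fixture_primer_pairs(fixture: Fixture) -> list[PrimerPair]:
    return [
        PrimerPair(
            marker_id=r.locus_id,
            forward=r.primer_forward,
            reverse=r.primer_reverse,
            expected_size=r.product_ref,
            expected_canonical_motif=r.canonical_motif,
        )
        for r in fixture.markers
    ]


@dataclass
class FixtureAnalysis:
    """Full pipeline output on a synthetic study, aligned with its truth."""

    comparisons: list[LocusComparison]
    ref_results: dict[str, SpecificityResult]
    alt_results: dict[str, SpecificityResult]
    n_markers: int
    n_confound_free: int
    n_agreeing: int

    @property
    def agreement_fraction(self) -> float:
        return self.n_agreeing / self.n_confound_free if self.n_confound_free else float("nan")


def analyze_fixture(
    fixture: Fixture,
    rules: BindingRules | None = None,
    scan_config: ScanConfig | None = None,
) -> FixtureAnalysis:
    """Run e-PCR on both genotypes and score against the truth table.

    Agreement is assessed on confound-free markers: those whose e-PCR was
    specific in both genotypes (multi-mapping primers or out-of-range
    products exclude themselves) and whose truth size difference is not the
    ambiguous 1 bp.  For each such marker the predicted polymorphism class
    and signed size change must equal the truth.
    """
    rules = rules or BindingRules()
    pairs = fixture_primer_pairs(fixture)
    ref_results = run_epcr(pairs, fixture.genome_ref, rules, scan_config)
    alt_results = run_epcr(pairs, fixture.genome_alt, rules, scan_config)
    comparisons = compare_runs(ref_results, alt_results)
    by_id = {c.marker_id: c for c in comparisons}

    n_confound_free = 0
    n_agreeing = 0
    for row in fixture.markers:
        comp = by_id[row.locus_id]
        if comp.polymorphism_class is PolymorphismClass.UNRESOLVED:
            continue  # e-PCR confound (multi-product, size out of range, ...)
        truth_delta = row.product_alt - row.product_ref
        if abs(truth_delta) == 1:
            continue  # ambiguous by construction
        n_confound_free += 1
        if (comp.delta_al_signed == truth_delta
                and comp.polymorphism_class.value == row.expected_class):
            n_agreeing += 1
    return FixtureAnalysis(
        comparisons=comparisons,
        ref_results=ref_results,
        alt_results=alt_results,
        n_markers=len(pairs),
        n_confound_free=n_confound_free,
        n_agreeing=n_agreeing,
    )
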