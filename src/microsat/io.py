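"""Tabular input/output: MISA-style locus tables, primer panels, reports."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .epcr import PrimerPair, SpecificityResult
from .polymorphism import CompoundKind, LocusComparison
from .scan import CompoundGroup, SSRLocus

__all__ = [
    "write_misa_tsv",
    "write_loci_tsv",
    "read_loci_tsv",
    "read_primer_tsv",
    "write_epcr_tsv",
    "read_comparison_tsv",
    "write_comparison_tsv",
]

MISA_COLUMNS = ["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"]


def write_misa_tsv(
    simple: Sequence[SSRLocus],
    compound: Sequence[CompoundGroup],
    path: str | Path,
) -> pd.DataFrame:
    """MISA-compatible locus table: one row per simple locus or compound.

    SSR type is ``p<period>`` for simple loci and ``c`` for compounds, whose
    notation concatenates member repeats with the interruption length, e.g.
    ``(AT)8_3_(GT)12``.
    """
    rows = []
    items: list[tuple[int, dict]] = []
    for l in simple:
        items.append((l.start, {
            "ID": l.seq_id, "SSR type": f"p{l.period}",
            "SSR": l.misa_notation(), "size": l.length,
            "start": l.start, "end": l.end, "_sid": l.seq_id,
        }))
    for g in compound:
        notation = g.members[0].misa_notation()
        for gap, member in zip(g.gaps, g.members[1:]):
            notation += f"_{gap}_{member.misa_notation()}"
        items.append((g.start, {
            "ID": g.seq_id, "SSR type": "c", "SSR": notation,
            "size": g.end - g.start + 1, "start": g.start, "end": g.end,
            "_sid": g.seq_id,
        }))
    items.sort(key=lambda x: (x[1]["_sid"], x[0]))
    for nr, (_, row) in enumerate(items, start=1):
        row.pop("_sid")
        row["SSR nr."] = nr
        rows.append(row)
    df = pd.DataFrame(rows, columns=MISA_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_loci_tsv(loci: Iterable[SSRLocus], path: str | Path) -> pd.DataFrame:
    """Rich per-locus table including the canonical motif and unit count."""
    df = pd.DataFrame(
        [
            {
                "seq_id": l.seq_id,
                "start": l.start,
                "end": l.end,
                "motif": l.motif,
                "canonical_motif": l.canonical_motif,
                "period": l.period,
                "repeat_units": l.repeat_units,
                "length": l.length,
                "compound_id": l.compound_id or "",
            }
            for l in loci
        ],
        columns=["seq_id", "start", "end", "motif", "canonical_motif",
                 "period", "repeat_units", "length", "compound_id"],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_loci_tsv(path: str | Path) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str},
                     keep_default_na=False)
    return [
        SSRLocus(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            motif=str(r.motif),
            canonical_motif=str(r.canonical_motif),
            repeat_units=int(r.repeat_units),
            length=int(r.length),
            compound_id=str(r.compound_id) or None,
        )
        for r in df.itertuples()
    ]


def read_primer_tsv(path: str | Path) -> list[PrimerPair]:
    """Primer panel: marker_id, forward, reverse[, expected_size, expected_motif]."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "forward", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer TSV missing columns: {sorted(missing)}")
    pairs = []
    for r in df.itertuples():
        size = getattr(r, "expected_size", None)
        motif = getattr(r, "expected_motif", None)
        pairs.append(
            PrimerPair(
                marker_id=str(r.marker_id),
                forward=str(r.forward).upper(),
                reverse=str(r.reverse).upper(),
                expected_size=int(size) if size is not None and pd.notna(size) else None,
                expected_canonical_motif=(str(motif) if motif is not None
                                          and pd.notna(motif) else None),
            )
        )
    return pairs


def write_epcr_tsv(results: dict[str, SpecificityResult], path: str | Path) -> pd.DataFrame:
    rows = []
    for marker_id in sorted(results):
        res = results[marker_id]
        amp = res.amplicon
        flanked = ",".join(l.canonical_motif for l in amp.flanked_ssrs) if amp else ""
        rows.append(
            {
                "marker_id": marker_id,
                "status": res.status.value,
                "seq_id": amp.seq_id if amp else "",
                "start": amp.start if amp else "",
                "end": amp.end if amp else "",
                "length": amp.length if amp else "",
                "n_mismatch_fwd": amp.forward_site.mismatches if amp else "",
                "n_mismatch_rev": amp.reverse_site.mismatches if amp else "",
                "flanked_motifs": flanked,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_comparison_tsv(comparisons: Iterable[LocusComparison], path: str | Path) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "marker_id": c.marker_id,
                "size_ref": c.size_ref if c.size_ref is not None else "",
                "size_alt": c.size_alt if c.size_alt is not None else "",
                "class": c.polymorphism_class.value,
                "delta_al_signed": c.delta_al_signed if c.delta_al_signed is not None else "",
                "direction": c.direction.value,
                "period": c.repeat_period if c.repeat_period is not None else "",
                "canonical_motif": c.canonical_motif or "",
                "repeat_units_ref": c.repeat_units_ref if c.repeat_units_ref is not None else "",
                "repeat_length_ref": c.repeat_length_ref if c.repeat_length_ref is not None else "",
                "compound": c.compound.value,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_comparison_tsv(path: str | Path) -> list[LocusComparison]:
    """Marker comparison table: marker_id, size_ref, size_alt + optional
    motif/period/unit metadata (supplementary-table style input)."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "size_ref", "size_alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"comparison TSV missing columns: {sorted(missing)}")

    def _opt_int(r, name):
        v = getattr(r, name, None)
        return int(v) if v is not None and pd.notna(v) and v != "" else None

    out = []
    for r in df.itertuples():
        motif = getattr(r, "canonical_motif", None)
        compound = getattr(r, "compound", CompoundKind.SIMPLE.value)
        out.append(
            LocusComparison(
                marker_id=str(r.marker_id),
                size_ref=_opt_int(r, "size_ref"),
                size_alt=_opt_int(r, "size_alt"),
                repeat_period=_opt_int(r, "period"),
                canonical_motif=str(motif) if motif is not None and pd.notna(motif) else None,
                repeat_units_ref=_opt_int(r, "repeat_units_ref"),
                repeat_length_ref=_opt_int(r, "repeat_length_ref"),
                compound=CompoundKind(compound) if pd.notna(compound) else CompoundKind.SIMPLE,
            )
        )
    return out
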