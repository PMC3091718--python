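"""Summary statistics for microsatellite surveys.

Conventions used throughout: SSR content is expressed as loci per million
base pairs (density), as relative frequencies (%) within a dataset, and as
mean repeat numbers (complete units only).  Reported percentages and
densities are rounded to one decimal; internal values keep full precision.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scan import SSRLocus, canonical_motif

__all__ = [
    "MotifClass",
    "TTestResult",
    "FrequencyTable",
    "density_per_mbp",
    "summarize_by_type",
    "repeat_unit_histogram",
    "classify_motif_at_content",
    "gc_content",
    "two_sample_t",
    "genome_fraction_pct",
]


class MotifClass(str, enum.Enum):
    """Base-composition class of a repeat motif."""

    AT_RICH = "AT-rich"
    BALANCED = "balanced"
    GC_RICH = "GC-rich"


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int


def density_per_mbp(count: int, total_bp: int) -> float:
    """SSR loci per million base pairs of analysed sequence."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (total_bp / 1e6)


def gc_content(sequence: str) -> float:
    """Percent G+C over unambiguous bases; NaN when no ACGT base exists."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def classify_motif_at_content(motif: str) -> MotifClass:
    """AT-rich / balanced / GC-rich by motif base counts alone."""
    m = motif.upper()
    at = m.count("A") + m.count("T")
    gc = m.count("G") + m.count("C")
    if at > gc:
        return MotifClass.AT_RICH
    if gc > at:
        return MotifClass.GC_RICH
    return MotifClass.BALANCED


@dataclass(frozen=True)
class FrequencyTable:
    """Per-period and per-motif summary of one SSR dataset.

    ``by_type`` is indexed by period with columns count, relative_frequency
    (%), mean_repeat_number, density (SSR/Mbp) and cumulative_length (bp);
    ``by_motif`` is indexed by canonical motif.  ``total_bp`` is the size of
    the sequence space the loci were mined from.
    """

    label: str
    total_bp: int
    by_type: pd.DataFrame
    by_motif: pd.DataFrame

    @property
    def total_count(self) -> int:
        return int(self.by_type["count"].sum())

    @property
    def total_density(self) -> float:
        return density_per_mbp(self.total_count, self.total_bp)

    def rounded(self) -> pd.DataFrame:
        """Report-ready per-type table with one-decimal percentages."""
        out = self.by_type.copy()
        for col in ("relative_frequency", "mean_repeat_number", "density"):
            out[col] = out[col].round(1)
        return out


def summarize_by_type(
    loci: Sequence[SSRLocus], total_bp: int, label: str = "dataset"
) -> FrequencyTable:
    """Tabulate counts, relative frequencies, densities and lengths by period.

    An empty locus list yields an all-zero table.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    periods = sorted({l.period for l in loci}) or []
    rows = []
    total = len(loci)
    for p in periods:
        sub = [l for l in loci if l.period == p]
        rows.append(
            {
                "period": p,
                "count": len(sub),
                "relative_frequency": 100.0 * len(sub) / total,
                "mean_repeat_number": float(np.mean([l.repeat_units for l in sub])),
                "density": density_per_mbp(len(sub), total_bp),
                "cumulative_length": int(sum(l.length for l in sub)),
            }
        )
    by_type = pd.DataFrame(
        rows,
        columns=["period", "count", "relative_frequency", "mean_repeat_number",
                 "density", "cumulative_length"],
    ).set_index("period")

    motif_rows = []
    if loci:
        counts: dict[str, int] = {}
        for l in loci:
            counts[l.canonical_motif] = counts.get(l.canonical_motif, 0) + 1
        for motif in sorted(counts, key=lambda m: (len(m), m)):
            motif_rows.append(
                {
                    "canonical_motif": motif,
                    "period": len(motif),
                    "count": counts[motif],
                    "density": density_per_mbp(counts[motif], total_bp),
                    "motif_class": classify_motif_at_content(motif).value,
                }
            )
    by_motif = pd.DataFrame(
        motif_rows,
        columns=["canonical_motif", "period", "count", "density", "motif_class"],
    ).set_index("canonical_motif")
    return FrequencyTable(label=label, total_bp=total_bp, by_type=by_type,
                          by_motif=by_motif)


def repeat_unit_histogram(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Relative frequency (%) of repeat-unit counts, per period.

    Returns a DataFrame with columns period, repeat_units, count and
    frequency, where frequency sums to 100% within each period.
    """
    if not loci:
        raise ValueError("repeat_unit_histogram needs at least one locus")
    df = pd.DataFrame(
        {"period": [l.period for l in loci], "repeat_units": [l.repeat_units for l in loci]}
    )
    counts = (
        df.groupby(["period", "repeat_units"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("period")["count"].transform("sum")
    counts["frequency"] = 100.0 * counts["count"] / totals
    return counts


def two_sample_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample Student t-test, two-sided.

    Degrees of freedom are n1 + n2 - 2.  Used to compare per-species SSR
    densities between genomic and transcript sequence.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(p):  # identical constant samples -> t = 0, p = 1
        t, p = 0.0, 1.0
    return TTestResult(t=t, p=p, df=df)


def genome_fraction_pct(
    counts: Mapping[int, int], mean_units: Mapping[int, float], total_bp: int
) -> float:
    """Percent of the sequence space occupied by SSR tracts.

    Estimated as sum over periods of count x mean repeat number x period,
    divided by the total analysed length.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    occupied = sum(counts[p] * mean_units[p] * p for p in counts)
    return 100.0 * occupied / total_bp
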