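"""Two-genotype SSR polymorphism analysis.

Each marker's amplicon length in a reference genotype is compared with the
length in an alternate genotype.  A marker is *monomorphic* when both
amplicons are identical, *polymorphic* when they differ by at least 2 bp,
and *ambiguous* at exactly 1 bp (such differences are indistinguishable from
sizing error and are excluded from every downstream table).  Markers that
could not be sized in one of the genotypes are *unresolved*, carried with a
missing-size sentinel rather than silently dropped.

The signed allele-length change delta_al = size_alt - size_ref; a negative
sign is a contraction of the repeat relative to the reference genotype.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import MotifClass, classify_motif_at_content

__all__ = [
    "PolymorphismClass",
    "Direction",
    "CompoundKind",
    "LocusComparison",
    "GroupTestResult",
    "REPEAT_LENGTH_BINS",
    "classify_polymorphism",
    "compound_repeat_units",
    "repeat_length_bin",
    "bin_by_repeat_length",
    "bin_margins",
    "expansion_contraction_profile",
    "correlate_delta_repeat",
    "anova_lsd",
]


class PolymorphismClass(str, enum.Enum):
    MONOMORPHIC = "monomorphic"
    POLYMORPHIC = "polymorphic"
    AMBIGUOUS = "ambiguous"
    UNRESOLVED = "unresolved"


class Direction(str, enum.Enum):
    EXPANSION = "expansion"
    CONTRACTION = "contraction"
    NONE = "none"


class CompoundKind(str, enum.Enum):
    SIMPLE = "simple"
    HOMOGENEOUS = "homogeneous_compound"
    HETEROGENEOUS = "heterogeneous_compound"


#: Repeat-tract length bins (nt): short, intermediate (both ends inclusive),
#: long.
REPEAT_LENGTH_BINS = ("<30", "30-40", ">40")


def classify_polymorphism(size_ref: int | None, size_alt: int | None) -> PolymorphismClass:
    """Classify one marker from its two amplicon sizes.

    A missing size on either side yields UNRESOLVED.
    """
    if size_ref is None or size_alt is None:
        return PolymorphismClass.UNRESOLVED
    if size_ref <= 0 or size_alt <= 0:
        raise ValueError("amplicon sizes must be positive")
    delta = abs(size_alt - size_ref)
    if delta == 0:
        return PolymorphismClass.MONOMORPHIC
    if delta == 1:
        return PolymorphismClass.AMBIGUOUS
    return PolymorphismClass.POLYMORPHIC


@dataclass(frozen=True)
class LocusComparison:
    """One marker's allele-length comparison between two genotypes."""

    marker_id: str
    size_ref: int | None
    size_alt: int | None
    repeat_period: int | None = None
    canonical_motif: str | None = None
    repeat_units_ref: int | None = None
    repeat_length_ref: int | None = None
    compound: CompoundKind = CompoundKind.SIMPLE

    @property
    def polymorphism_class(self) -> PolymorphismClass:
        return classify_polymorphism(self.size_ref, self.size_alt)

    @property
    def delta_al_signed(self) -> int | None:
        if self.size_ref is None or self.size_alt is None:
            return None
        return self.size_alt - self.size_ref

    @property
    def delta_al_magnitude(self) -> int | None:
        d = self.delta_al_signed
        return None if d is None else abs(d)

    @property
    def direction(self) -> Direction:
        d = self.delta_al_signed
        if d is None or d == 0:
            return Direction.NONE
        return Direction.CONTRACTION if d < 0 else Direction.EXPANSION

    @property
    def motif_class(self) -> MotifClass | None:
        if self.canonical_motif is None:
            return None
        return classify_motif_at_content(self.canonical_motif)

    def swapped(self) -> "LocusComparison":
        """Reference/alternate roles exchanged (sign convention check)."""
        return LocusComparison(
            marker_id=self.marker_id,
            size_ref=self.size_alt,
            size_alt=self.size_ref,
            repeat_period=self.repeat_period,
            canonical_motif=self.canonical_motif,
            repeat_units_ref=self.repeat_units_ref,
            repeat_length_ref=self.repeat_length_ref,
            compound=self.compound,
        )


def compound_repeat_units(
    members: Sequence[tuple[str, int]],
    dinucleotide_only: bool = False,
    min_total: int = 10,
) -> int | None:
    """Summed repeat units of a compound allele, or None when ineligible.

    Units of each uninterrupted member repeat are summed when the total
    reaches ``min_total`` (e.g. (AT)8(GT)12 -> 20).  With
    ``dinucleotide_only`` the compound qualifies only when every member is a
    dinucleotide (used for dinucleotide-restricted analyses).  A single
    member is returned as-is when it meets the total.
    """
    if not members:
        raise ValueError("compound allele needs at least one member")
    if dinucleotide_only and any(len(motif) != 2 for motif, _ in members):
        return None
    total = sum(units for _, units in members)
    if total < min_total:
        return None
    return total


def repeat_length_bin(length_nt: int) -> str:
    """<30 / 30-40 (inclusive) / >40 nt."""
    if length_nt < 30:
        return REPEAT_LENGTH_BINS[0]
    if length_nt <= 40:
        return REPEAT_LENGTH_BINS[1]
    return REPEAT_LENGTH_BINS[2]


def bin_by_repeat_length(comparisons: Iterable[LocusComparison]) -> pd.DataFrame:
    """Counts of monomorphic/polymorphic loci by repeat-length bin and period.

    Heterogeneous compound loci cannot be assigned a repeat-type class and
    are excluded, as are ambiguous and unresolved markers.  Binning uses the
    reference-genotype repeat tract length (markers are designed from the
    reference).  The result is indexed by (class, period) with one column
    per bin plus a total.
    """
    rows = []
    for c in comparisons:
        cls = c.polymorphism_class
        if cls not in (PolymorphismClass.MONOMORPHIC, PolymorphismClass.POLYMORPHIC):
            continue
        if c.compound is CompoundKind.HETEROGENEOUS:
            continue
        if c.repeat_length_ref is None or c.repeat_period is None:
            continue
        rows.append(
            {
                "class": cls.value,
                "period": c.repeat_period,
                "bin": repeat_length_bin(c.repeat_length_ref),
            }
        )
    if not rows:
        return pd.DataFrame(columns=[*REPEAT_LENGTH_BINS, "total"])
    df = pd.DataFrame(rows)
    table = (
        df.pivot_table(index=["class", "period"], columns="bin", aggfunc="size",
                       fill_value=0)
        .reindex(columns=list(REPEAT_LENGTH_BINS), fill_value=0)
    )
    table.columns.name = None
    table["total"] = table.sum(axis=1)
    return table


def bin_margins(table: pd.DataFrame, cls: str) -> pd.Series:
    """Column totals and their percentages for one polymorphism class.

    Returns a Series with counts per bin plus ``pct_<bin>`` entries rounded
    to one decimal (row-margin style of a frequency table).
    """
    sub = table.loc[cls]
    counts = sub[list(REPEAT_LENGTH_BINS)].sum()
    total = counts.sum()
    out = counts.astype(int).to_dict()
    for b in REPEAT_LENGTH_BINS:
        out[f"pct_{b}"] = round(100.0 * counts[b] / total, 1) if total else float("nan")
    out["total"] = int(total)
    return pd.Series(out)


def expansion_contraction_profile(
    comparisons: Iterable[LocusComparison],
    unit_classes: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Expansion/contraction frequencies and delta_al magnitude per unit class.

    Only polymorphic loci are profiled; unit classes are (low, high)
    inclusive bounds on the reference-genotype repeat-unit count.  Per class
    the expansion and contraction percentages sum to 100; mean and standard
    deviation of the delta_al magnitude are included.  Classes with no locus
    are omitted.
    """
    polys = [
        c for c in comparisons
        if c.polymorphism_class is PolymorphismClass.POLYMORPHIC
        and c.repeat_units_ref is not None
    ]
    rows = []
    for lo, hi in unit_classes:
        sub = [c for c in polys if lo <= c.repeat_units_ref <= hi]
        if not sub:
            continue
        n_exp = sum(1 for c in sub if c.direction is Direction.EXPANSION)
        n_con = sum(1 for c in sub if c.direction is Direction.CONTRACTION)
        mags = np.array([c.delta_al_magnitude for c in sub], dtype=float)
        rows.append(
            {
                "unit_class": f"{lo}-{hi}",
                "lo": lo,
                "hi": hi,
                "n": len(sub),
                "n_expansion": n_exp,
                "n_contraction": n_con,
                "pct_expansion": 100.0 * n_exp / (n_exp + n_con),
                "pct_contraction": 100.0 * n_con / (n_exp + n_con),
                "mean_delta_al": float(mags.mean()),
                "sd_delta_al": float(mags.std(ddof=1)) if len(sub) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def correlate_delta_repeat(
    comparisons: Iterable[LocusComparison],
    periods: Sequence[int] | None = None,
    signed: bool = False,
) -> tuple[float, float]:
    """Pearson correlation of delta_al with the reference repeat-unit count.

    Polymorphic loci only; ``periods`` restricts to given motif lengths
    (e.g. ``[2]`` for the dinucleotide analysis).  The default correlate is
    the magnitude of delta_al; the signed value is available but
    non-default.  The p-value is two-sided via the t transform with n-2
    degrees of freedom.
    """
    xs, ys = [], []
    for c in comparisons:
        if c.polymorphism_class is not PolymorphismClass.POLYMORPHIC:
            continue
        if c.repeat_units_ref is None:
            continue
        if periods is not None and c.repeat_period not in periods:
            continue
        xs.append(c.repeat_units_ref)
        ys.append(c.delta_al_signed if signed else c.delta_al_magnitude)
    if len(xs) < 3:
        raise ValueError("need at least 3 polymorphic loci after filtering")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xs, ys)
    return float(r), float(p)


@dataclass(frozen=True)
class GroupTestResult:
    """One-way ANOVA with Fisher's LSD pairwise comparisons at alpha=0.05."""

    means: dict[str, float]
    f: float
    p: float
    df_between: int
    df_within: int
    mse: float
    pairwise: dict[tuple[str, str], tuple[float, bool]]  # (p, significant)

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, (_, sig) in self.pairwise.items() if sig]


def anova_lsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA followed by Fisher's least-significant-difference test.

    Pairwise comparisons use t = |mi - mj| / sqrt(MSE (1/ni + 1/nj)) on the
    pooled within-group mean square with N - k degrees of freedom;
    significance is symmetric and assessed at ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(groups[g], dtype=float) for g in labels}
    if any(v.size < 2 for v in data.values()):
        raise ValueError("every group needs n >= 2")
    k = len(labels)
    n_total = sum(v.size for v in data.values())
    f, p = sps.f_oneway(*data.values())
    df_within = n_total - k
    mse = sum((v.size - 1) * v.var(ddof=1) for v in data.values()) / df_within
    means = {g: float(v.mean()) for g, v in data.items()}
    pairwise: dict[tuple[str, str], tuple[float, bool]] = {}
    for a, b in itertools.combinations(labels, 2):
        na, nb = data[a].size, data[b].size
        if mse == 0:
            diff = abs(means[a] - means[b])
            p_ab = 1.0 if diff == 0 else 0.0
        else:
            t_ab = abs(means[a] - means[b]) / math.sqrt(mse * (1 / na + 1 / nb))
            p_ab = 2.0 * sps.t.sf(t_ab, df_within)
        pairwise[(a, b)] = (float(p_ab), p_ab < alpha)
    return GroupTestResult(
        means=means,
        f=float(f),
        p=float(p),
        df_between=k - 1,
        df_within=df_within,
        mse=float(mse),
        pairwise=pairwise,
    )
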