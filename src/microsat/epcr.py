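"""In-silico (electronic) PCR against an assembly.

A primer is allowed to anneal wherever three constraints hold simultaneously:
mismatches are confined to a short 5' window (default: the 5'-most 5
positions, at most 5 of them), every base from the end of that window to the
3' terminus matches exactly, and overall identity over the full primer length
is at least 80%.  Convergent forward/reverse sites on one sequence whose
product length falls within the retained range (default 100-2000 bp) yield
predicted amplicons; a marker is *specific* when exactly one amplicon is
produced, its span does not exceed the span limit (default 4 kb) and it
flanks an SSR of the expected canonical motif.

Only substitutions are modelled at the annealing step (no indels), matching
how such primer screens are conventionally run.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scan import ScanConfig, SSRLocus, canonical_motif, find_perfect_ssrs, reverse_complement

__all__ = [
    "BindingRules",
    "PrimerPair",
    "BindingSite",
    "Amplicon",
    "SpecificityStatus",
    "SpecificityResult",
    "find_binding_sites",
    "predict_amplicons",
    "classify_specificity",
    "single_copy_filter",
    "run_epcr",
]

PRIMER_MIN_LEN = 15
PRIMER_MAX_LEN = 36


@dataclass(frozen=True)
class BindingRules:
    """Primer-annealing admissibility rules.

    ``five_prime_window`` positions at the 5' end may carry up to
    ``max_mismatches`` substitutions; the remainder of the primer, through
    the 3' terminus, must match exactly; overall identity (matches over full
    primer length) must reach ``min_identity``.
    """

    five_prime_window: int = 5
    max_mismatches: int = 5
    min_identity: float = 0.8
    min_product: int = 100
    max_product: int = 2000
    max_span: int = 4000

    def __post_init__(self) -> None:
        if self.five_prime_window < 0 or self.max_mismatches < 0:
            raise ValueError("window and mismatch limits must be >= 0")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_product > self.max_product:
            raise ValueError("min_product must be <= max_product")


@dataclass(frozen=True)
class PrimerPair:
    """A marker's two primers, both written 5'->3'."""

    marker_id: str
    forward: str
    reverse: str
    expected_size: int | None = None
    expected_canonical_motif: str | None = None

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not (PRIMER_MIN_LEN <= len(p) <= PRIMER_MAX_LEN):
                raise ValueError(
                    f"{self.marker_id}: {name} primer length {len(p)} outside "
                    f"[{PRIMER_MIN_LEN}, {PRIMER_MAX_LEN}]"
                )
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{self.marker_id}: {name} primer has non-ACGT bases")


@dataclass(frozen=True)
class BindingSite:
    """An admissible primer match on one strand of one sequence.

    ``start``/``end`` are the 1-based inclusive footprint on the forward
    coordinate system; ``mismatch_positions`` are primer-relative indices
    counted from the primer's 5' end (0-based).
    """

    seq_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[int, ...] = ()

    @property
    def three_prime_pos(self) -> int:
        """Forward-strand coordinate of the primer's 3' terminal base."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product between convergent primer sites."""

    seq_id: str
    start: int
    end: int
    length: int
    forward_site: BindingSite
    reverse_site: BindingSite
    flanked_ssrs: tuple[SSRLocus, ...] = ()


class SpecificityStatus(str, enum.Enum):
    SPECIFIC = "specific"
    NO_AMPLIFICATION = "no_amplification"
    MULTI_PRODUCT = "multi_product"
    MOTIF_MISMATCH = "motif_mismatch"
    NONSPECIFIC = "nonspecific"


@dataclass(frozen=True)
class SpecificityResult:
    marker_id: str
    status: SpecificityStatus
    amplicon: Amplicon | None = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def find_binding_sites(
    primer: str,
    sequences: Mapping[str, str],
    rules: BindingRules | None = None,
) -> list[BindingSite]:
    """Every admissible binding site of one primer, both strands.

    Reverse-strand sites are evaluated against the reverse complement; their
    footprint is reported in forward coordinates with strand '-'.  Output is
    deterministic: sorted by (seq_id, start, strand).
    """
    rules = rules or BindingRules()
    primer = primer.upper()
    L = len(primer)
    if L <= rules.five_prime_window:
        raise ValueError("primer shorter than the 3'-exact window requires")
    if not (PRIMER_MIN_LEN <= L <= PRIMER_MAX_LEN):
        raise ValueError(f"primer length {L} outside [{PRIMER_MIN_LEN}, {PRIMER_MAX_LEN}]")
    # identity floor: (L - mm)/L >= min_identity, with an epsilon so an
    # exactly-attained threshold (e.g. 16/20 = 80%) stays admissible
    max_mm = min(rules.max_mismatches, rules.five_prime_window,
                 int(np.floor((1.0 - rules.min_identity) * L + 1e-9)))

    sites: list[BindingSite] = []
    for seq_id, seq in sequences.items():
        seq_arr = _encode(seq)
        n = seq_arr.size
        if n < L:
            continue
        n_pos = n - L + 1
        for strand in ("+", "-"):
            # Orient the primer onto the forward coordinate system.  On '+'
            # the primer reads left->right (5' at footprint start); on '-'
            # its reverse complement reads left->right (5' at footprint end).
            oriented = primer if strand == "+" else reverse_complement(primer)
            p_arr = _encode(oriented)
            mism = np.zeros(n_pos, dtype=np.int32)
            per_k = []
            for k in range(L):
                neq = seq_arr[k : k + n_pos] != p_arr[k]
                per_k.append(neq)
                mism += neq
            # primer-relative index (from its own 5' end) of oriented pos k
            rel = (lambda k: k) if strand == "+" else (lambda k: L - 1 - k)
            # mismatches outside the 5' window must be zero
            tail_mism = np.zeros(n_pos, dtype=np.int32)
            for k in range(L):
                if rel(k) >= rules.five_prime_window:
                    tail_mism += per_k[k]
            ok = (mism <= max_mm) & (tail_mism == 0)
            for pos in np.flatnonzero(ok):
                mm_pos = tuple(
                    sorted(rel(k) for k in range(L) if per_k[k][pos])
                )
                sites.append(
                    BindingSite(
                        seq_id=seq_id,
                        strand=strand,
                        start=int(pos) + 1,
                        end=int(pos) + L,
                        mismatches=int(mism[pos]),
                        mismatch_positions=mm_pos,
                    )
                )
    sites.sort(key=lambda s: (s.seq_id, s.start, s.strand))
    return sites


def predict_amplicons(
    pair: PrimerPair,
    sequences: Mapping[str, str],
    rules: BindingRules | None = None,
    scan_config: ScanConfig | None = None,
) -> list[Amplicon]:
    """Predicted products for one primer pair against an assembly.

    Every convergent combination of a forward-primer site and a
    reverse-primer site on the same sequence, with non-overlapping
    footprints and outer-to-outer length within [min_product, max_product],
    is returned.  Either primer may seed either strand (products are
    orientation-symmetric).  ``flanked_ssrs`` holds perfect repeats located
    strictly between the two footprints.
    """
    rules = rules or BindingRules()
    fwd_sites = find_binding_sites(pair.forward, sequences, rules)
    rev_sites = find_binding_sites(pair.reverse, sequences, rules)

    amps: list[Amplicon] = []
    # (left primer on '+', right primer on '-') in both primer assignments
    for left_list, right_list in ((fwd_sites, rev_sites), (rev_sites, fwd_sites)):
        for ls in left_list:
            if ls.strand != "+":
                continue
            for rs in right_list:
                if rs.strand != "-" or rs.seq_id != ls.seq_id:
                    continue
                if rs.start <= ls.end:  # overlapping or divergent footprints
                    continue
                length = rs.end - ls.start + 1
                if not (rules.min_product <= length <= rules.max_product):
                    continue
                inner = sequences[ls.seq_id][ls.end : rs.start - 1]
                inner_loci = tuple(
                    SSRLocus(
                        seq_id=ls.seq_id,
                        start=l.start + ls.end,
                        end=l.end + ls.end,
                        motif=l.motif,
                        canonical_motif=l.canonical_motif,
                        repeat_units=l.repeat_units,
                        length=l.length,
                    )
                    for l in find_perfect_ssrs(inner, scan_config, seq_id=ls.seq_id)
                )
                amps.append(
                    Amplicon(
                        seq_id=ls.seq_id,
                        start=ls.start,
                        end=rs.end,
                        length=length,
                        forward_site=ls,
                        reverse_site=rs,
                        flanked_ssrs=inner_loci,
                    )
                )
    # de-duplicate products found under both primer assignments (palindromic
    # or identical primers), then order deterministically
    uniq: dict[tuple[str, int, int], Amplicon] = {}
    for a in amps:
        uniq.setdefault((a.seq_id, a.start, a.end), a)
    out = list(uniq.values())
    out.sort(key=lambda a: (a.seq_id, a.start, a.end))
    return out


def classify_specificity(
    pair: PrimerPair,
    amplicons: Sequence[Amplicon],
    expected_canonical_motif: str | None = None,
    rules: BindingRules | None = None,
) -> SpecificityResult:
    """Specific / no_amplification / multi_product / motif_mismatch.

    A marker is specific when exactly one product exists, its span is within
    the limit, and at least one flanked SSR carries the expected canonical
    motif.
    """
    rules = rules or BindingRules()
    expected = expected_canonical_motif or pair.expected_canonical_motif
    if expected is None:
        raise ValueError(f"{pair.marker_id}: expected canonical motif required")
    expected = canonical_motif(expected)
    if len(amplicons) == 0:
        return SpecificityResult(pair.marker_id, SpecificityStatus.NO_AMPLIFICATION)
    if len(amplicons) > 1:
        return SpecificityResult(pair.marker_id, SpecificityStatus.MULTI_PRODUCT)
    amp = amplicons[0]
    if amp.length > rules.max_span:
        return SpecificityResult(pair.marker_id, SpecificityStatus.NONSPECIFIC, amp)
    if any(l.canonical_motif == expected for l in amp.flanked_ssrs):
        return SpecificityResult(pair.marker_id, SpecificityStatus.SPECIFIC, amp)
    return SpecificityResult(pair.marker_id, SpecificityStatus.MOTIF_MISMATCH, amp)


def single_copy_filter(results: Iterable[SpecificityResult]) -> list[str]:
    """Marker ids whose e-PCR outcome was specific (single-copy markers)."""
    return [r.marker_id for r in results if r.status is SpecificityStatus.SPECIFIC]


def run_epcr(
    pairs: Iterable[PrimerPair],
    sequences: Mapping[str, str],
    rules: BindingRules | None = None,
    scan_config: ScanConfig | None = None,
) -> dict[str, SpecificityResult]:
    """Classify every marker of a panel against one assembly."""
    rules = rules or BindingRules()
    out: dict[str, SpecificityResult] = {}
    for pair in pairs:
        amps = predict_amplicons(pair, sequences, rules, scan_config)
        out[pair.marker_id] = classify_specificity(pair, amps, rules=rules)
    return out
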