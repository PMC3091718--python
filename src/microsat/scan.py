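"""Detection of perfect microsatellites (SSRs) in DNA sequence.

A microsatellite is a tandem repeat of a short motif (here 2-8 bp).  Only
*perfect* repeats are considered: consecutive exact copies of the motif with
no substitutions, insertions or interruptions.  Mononucleotide runs are never
reported because in shotgun assemblies they are hard to distinguish from
sequencing error (and poly-A/T tracts in transcripts may be polyadenylation
artifacts rather than genomic repeats).

Motifs are reported both as they occur on the scanned strand and as a
*canonical* class label: the lexicographically smallest string among all
rotations of the motif and all rotations of its reverse complement, so that
AC, CA, GT and TG all tally under "AC".  This makes frequency tables
strand-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "ScanConfig",
    "SSRLocus",
    "CompoundGroup",
    "FastaRecordStats",
    "canonical_motif",
    "is_primitive_motif",
    "reverse_complement",
    "find_perfect_ssrs",
    "group_compound_ssrs",
    "scan_fasta",
    "DEFAULT_MIN_LENGTH_BY_PERIOD",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Minimum total tract length (bp) required per motif period.  Di- to
#: tetranucleotides need 12 bp; longer motifs need 3 full units
#: (15/18/21/24 bp for period 5/6/7/8).
DEFAULT_MIN_LENGTH_BY_PERIOD: dict[int, int] = {
    2: 12, 3: 12, 4: 12, 5: 15, 6: 18, 7: 21, 8: 24,
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds controlling the perfect-repeat search.

    Parameters
    ----------
    min_period, max_period
        Inclusive range of motif lengths searched (defaults 2-8).
    min_repeat_units
        Minimum number of complete motif copies (default 3).
    min_total_length_by_period
        Minimum tract length in bp for each period.
    compound_max_gap
        Maximum interruption (bp) between neighbouring loci merged into one
        compound SSR.
    """

    min_period: int = 2
    max_period: int = 8
    min_repeat_units: int = 3
    min_total_length_by_period: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_LENGTH_BY_PERIOD)
    )
    compound_max_gap: int = 100

    def __post_init__(self) -> None:
        if self.min_period < 1:
            raise ValueError("min_period must be >= 1")
        if self.max_period < self.min_period:
            raise ValueError("max_period must be >= min_period")
        if self.min_repeat_units < 1:
            raise ValueError("min_repeat_units must be >= 1")
        if self.compound_max_gap < 0:
            raise ValueError("compound_max_gap must be >= 0")
        for p in range(self.min_period, self.max_period + 1):
            if p not in self.min_total_length_by_period:
                raise ValueError(f"no minimum length configured for period {p}")

    def min_length(self, period: int) -> int:
        return self.min_total_length_by_period[period]


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite tract.

    Coordinates are 1-based and fully closed (MISA-compatible).  The locus
    spans exactly ``repeat_units`` complete motif copies; a trailing partial
    copy is never included, so ``length == repeat_units * len(motif)``.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    repeat_units: int
    length: int
    compound_id: str | None = None

    @property
    def period(self) -> int:
        return len(self.motif)

    def misa_notation(self) -> str:
        return f"({self.motif}){self.repeat_units}"


@dataclass(frozen=True)
class CompoundGroup:
    """Two or more SSR loci separated by interruptions <= compound_max_gap."""

    members: tuple[SSRLocus, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a compound group needs at least 2 members")
        if len({m.seq_id for m in self.members}) != 1:
            raise ValueError("compound members must share a seq_id")

    @property
    def seq_id(self) -> str:
        return self.members[0].seq_id

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def heterogeneous(self) -> bool:
        """True when member motifs differ (by canonical class)."""
        return len({m.canonical_motif for m in self.members}) > 1


def _check_alphabet(motif: str) -> str:
    m = motif.upper()
    if not m:
        raise ValueError("empty motif")
    bad = set(m) - set("ACGT")
    if bad:
        raise ValueError(f"motif contains non-ACGT characters: {sorted(bad)}")
    return m


def canonical_motif(motif: str) -> str:
    """Class representative of a motif under rotation and reverse complement.

    Returns the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement, e.g. GT -> AC and
    CTT -> AAG.  Idempotent, and identical for every member of the class.
    """
    m = _check_alphabet(motif)
    if len(m) > 8:
        raise ValueError("motif longer than 8 bp")
    rc = reverse_complement(m)
    candidates = [m[i:] + m[:i] for i in range(len(m))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def is_primitive_motif(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter one.

    AT is primitive; ATAT is not (AT twice).  Needed so a poly-AT tract is
    never reported as an (ATAT)n tetranucleotide.
    """
    m = _check_alphabet(motif)
    n = len(m)
    for d in range(1, n):
        if n % d == 0 and m[: d] * (n // d) == m:
            return False
    return True


def _find_ssrs_one_period(seq: str, valid: np.ndarray, arr: np.ndarray,
                          period: int, cfg: ScanConfig) -> list[tuple[int, int, str, int]]:
    """Candidate loci for one period as (start0, end0_exclusive, motif, units)."""
    n = len(seq)
    if n < period * cfg.min_repeat_units:
        return []
    # eq[j] is True when position j matches position j+period and both are ACGT
    eq = (arr[:-period] == arr[period:]) & valid[:-period] & valid[period:]
    if not eq.any():
        return []
    out: list[tuple[int, int, str, int]] = []
    # maximal runs of True in eq
    idx = np.flatnonzero(np.diff(np.concatenate(([False], eq, [False])).view(np.int8)))
    for a, b in zip(idx[::2], idx[1::2]):
        m = int(b - a)                      # matching positions
        region_len = m + period             # perfect-tract length incl. first unit
        units = region_len // period        # complete copies only
        if units < cfg.min_repeat_units:
            continue
        length = units * period
        if length < cfg.min_length(period):
            continue
        motif = seq[a : a + period]
        if not is_primitive_motif(motif):
            continue  # reported at its true (smaller) period instead
        out.append((int(a), int(a) + length, motif, units))
    return out


def find_perfect_ssrs(sequence: str, config: ScanConfig | None = None,
                      seq_id: str = "seq") -> list[SSRLocus]:
    """All maximal perfect tandem repeats in ``sequence`` passing thresholds.

    The search is strand-specific (the reverse complement of the input yields
    the same canonical classes and unit counts).  Input is upper-cased;
    any non-ACGT character (N etc.) terminates a repeat.  A locus is maximal:
    its perfect tract cannot be extended by a full unit on either side.  When
    shifted alignments of the same tract compete, the leftmost start wins.
    Loci of a larger period are never reported nested inside a reported
    smaller-period locus.  Result sorted by (start, end).
    """
    cfg = config or ScanConfig()
    seq = sequence.upper()
    if not seq:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))

    candidates: list[tuple[int, int, str, int]] = []
    for period in range(max(2, cfg.min_period), cfg.max_period + 1):
        candidates.extend(_find_ssrs_one_period(seq, valid, arr, period, cfg))

    # Drop any candidate fully nested inside an accepted smaller-period locus.
    # (Primitivity makes this provably impossible for true sub-tracts, but the
    # guard keeps the output contract explicit and costs nothing.)
    candidates.sort(key=lambda c: (len(c[2]), c[0]))
    accepted: list[tuple[int, int, str, int]] = []
    for cand in candidates:
        a, b, motif, units = cand
        nested = any(a >= a2 and b <= b2 and len(motif) > len(m2)
                     for a2, b2, m2, _ in accepted)
        if not nested:
            accepted.append(cand)

    loci = [
        SSRLocus(
            seq_id=seq_id,
            start=a + 1,
            end=a + len(motif) * units,
            motif=motif,
            canonical_motif=canonical_motif(motif),
            repeat_units=units,
            length=len(motif) * units,
        )
        for a, b, motif, units in accepted
    ]
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


def group_compound_ssrs(
    loci: Iterable[SSRLocus], max_gap: int = 100
) -> tuple[list[SSRLocus], list[CompoundGroup]]:
    """Partition loci into simple SSRs and compound groups.

    Consecutive loci on the same sequence separated by at most ``max_gap``
    interrupting bases are chained into one compound group.  Input is sorted
    internally by (seq_id, start, end), so unsorted input is never
    mis-grouped.  The returned partition is complete and disjoint; members of
    a compound are labelled with a shared ``compound_id``.
    """
    ordered = sorted(loci, key=lambda l: (l.seq_id, l.start, l.end))
    simple: list[SSRLocus] = []
    compound: list[CompoundGroup] = []

    def _flush(chain: list[SSRLocus], gaps: list[int]) -> None:
        if len(chain) == 1:
            simple.append(chain[0])
        else:
            cid = f"{chain[0].seq_id}:{chain[0].start}-{chain[-1].end}"
            members = tuple(replace(m, compound_id=cid) for m in chain)
            compound.append(CompoundGroup(members=members, gaps=tuple(gaps)))

    chain: list[SSRLocus] = []
    gaps: list[int] = []
    for locus in ordered:
        if not chain:
            chain = [locus]
            continue
        prev = chain[-1]
        gap = locus.start - prev.end - 1
        if locus.seq_id == prev.seq_id and gap <= max_gap:
            chain.append(locus)
            gaps.append(gap)
        else:
            _flush(chain, gaps)
            chain, gaps = [locus], []
    if chain:
        _flush(chain, gaps)
    return simple, compound


@dataclass(frozen=True)
class FastaRecordStats:
    """Per-record bookkeeping accumulated while scanning a FASTA file."""

    seq_id: str
    length: int
    acgt: int
    gc: int

    @property
    def gc_fraction(self) -> float:
        """G+C over A+C+G+T; NaN when the record has no unambiguous base."""
        return self.gc / self.acgt if self.acgt else float("nan")


def scan_fasta(
    path: str | Path, config: ScanConfig | None = None
) -> Iterator[tuple[FastaRecordStats, list[SSRLocus]]]:
    """Scan every record of a (multi-)FASTA file for perfect SSRs.

    Yields ``(record_stats, loci)`` per record, with seq_id taken from the
    first whitespace-delimited token of the header.  Ambiguity codes are
    excluded from both numerator and denominator of the GC fraction.
    """
    cfg = config or ScanConfig()
    path = Path(path)
    try:
        records = SeqIO.parse(str(path), "fasta")
        for rec in records:
            seq = str(rec.seq).upper()
            acgt = sum(seq.count(b) for b in "ACGT")
            gc = seq.count("G") + seq.count("C")
            stats = FastaRecordStats(seq_id=rec.id, length=len(seq), acgt=acgt, gc=gc)
            yield stats, find_perfect_ssrs(seq, cfg, seq_id=rec.id)
    except FileNotFoundError:
        raise
    except (OSError, ValueError) as exc:
        raise IOError(f"failed to parse FASTA {path}: {exc}") from exc
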