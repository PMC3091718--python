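"""Synthetic paired-genotype genomes with implanted microsatellites.

The generator produces everything the rest of the package consumes, with
machine-readable ground truth: a repeat-free background sequence of
configurable GC content, implanted perfect SSRs whose period and motif
frequencies mirror a plant genome in which AT-rich motifs dominate and
dinucleotides carry far more repeat units than longer motifs, a second
"genotype" derived from the first by per-locus repeat-unit expansions and
contractions under a slippage-style mutation model in which the contraction
probability rises with repeat length, and flanking primer pairs for each
locus.  Every artifact is a pure function of (spec, seed).

The reference genotype plays the role of the genome the markers were
designed from; the alternate genotype is the one screened by in-silico PCR.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .scan import (
    ScanConfig,
    canonical_motif,
    find_perfect_ssrs,
    reverse_complement,
)
from .polymorphism import classify_polymorphism

__all__ = [
    "GenomeSpec",
    "ImplantSampling",
    "Implant",
    "MutationModel",
    "PrimerDesignRules",
    "TruthRow",
    "Fixture",
    "generate_background",
    "sample_implants",
    "implant_ssrs",
    "mutate_genotype",
    "design_flank_primers",
    "build_fixture",
    "emit_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Background-genome parameters.

    GC defaults to 0.323, the composition of the cucumber assembly this
    pipeline is modelled on.
    """

    n_scaffolds: int = 4
    scaffold_length: int = 30_000
    gc: float = 0.323
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError("scaffold count and length must be positive")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")


# Motif frequencies per period, loosely shaped on a genome-wide AT-rich plant
# survey (AT dominating dinucleotides; AAT/AAG the common trinucleotides;
# AAAT-type motifs leading at period 4+; CG-rich motifs rare).
_DEFAULT_MOTIF_WEIGHTS: dict[int, dict[str, float]] = {
    2: {"AT": 0.70, "AG": 0.17, "AC": 0.12, "CG": 0.01},
    3: {"AAT": 0.38, "AAG": 0.30, "ATC": 0.10, "AAC": 0.08, "ACC": 0.06,
        "AGG": 0.04, "ACG": 0.02, "CCG": 0.02},
    4: {"AAAT": 0.45, "AAAG": 0.20, "AATT": 0.15, "AAAC": 0.10, "AATG": 0.06,
        "ACAT": 0.04},
    5: {"AAAAG": 0.30, "AAAAT": 0.30, "AAATT": 0.20, "AAAAC": 0.10,
        "AATAT": 0.10},
    6: {"AAAAAG": 0.35, "AAAAAT": 0.30, "AAAAAC": 0.15, "AAAATT": 0.20},
    7: {"AAAAAAG": 0.40, "AAAAAAT": 0.40, "AAAAAAC": 0.20},
    8: {"AAAAAAAG": 0.40, "AAAGAGAG": 0.25, "AAAAAAAT": 0.35},
}

# Period sampling weights mirroring the genomic relative frequencies
# (tetra > di > tri >> penta > hexa > hepta > octa).
_DEFAULT_PERIOD_WEIGHTS: dict[int, float] = {
    2: 0.265, 3: 0.256, 4: 0.298, 5: 0.098, 6: 0.056, 7: 0.021, 8: 0.007,
}

# Geometric(p) parameters for the repeat-unit count above the per-period
# minimum, tuned so mean unit counts track a genomic survey: dinucleotides
# ~9.6 units, trinucleotides ~4.9, longer motifs ~3.2.
_DEFAULT_UNIT_GEOM_P: dict[int, float] = {
    2: 0.217, 3: 0.526, 4: 0.833, 5: 0.833, 6: 0.833, 7: 0.833, 8: 0.833,
}
_MIN_UNITS: dict[int, int] = {2: 6, 3: 4, 4: 3, 5: 3, 6: 3, 7: 3, 8: 3}


@dataclass(frozen=True)
class ImplantSampling:
    """How loci are drawn when no explicit implant list is given."""

    n_loci: int = 240
    period_weights: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PERIOD_WEIGHTS))
    motif_weights: dict[int, dict[str, float]] = field(
        default_factory=lambda: {p: dict(w) for p, w in _DEFAULT_MOTIF_WEIGHTS.items()})
    unit_geom_p: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_UNIT_GEOM_P))
    min_units: dict[int, int] = field(default_factory=lambda: dict(_MIN_UNITS))
    max_units: int = 40
    spacing: int = 450     # distance between successive implant starts
    margin: int = 350      # repeat-free scaffold ends, room for primers


@dataclass(frozen=True)
class Implant:
    """One locus to implant: motif as it will appear on the forward strand."""

    seq_id: str
    position: int  # 0-based start in the background sequence
    motif: str
    repeat_units: int


@dataclass(frozen=True)
class MutationModel:
    """Slippage-style repeat-length mutation between the two genotypes.

    A locus mutates with probability ``p_change``.  The mutation direction
    is a contraction with probability ``logistic(intercept + slope*units)``
    (non-decreasing in the unit count for slope >= 0, emulating the
    tendency of long repeats to shrink), otherwise an expansion.  The step
    size in units is geometric with parameter ``step_geom_p``.  A step that
    would leave fewer than one unit is redrawn; if no contraction step is
    feasible the locus expands instead.
    """

    p_change: float = 0.55
    contraction_intercept: float = -2.0
    contraction_slope: float = 0.25
    step_geom_p: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_change <= 1.0):
            raise ValueError("p_change must be in [0, 1]")
        if self.contraction_slope < 0:
            raise ValueError("contraction probability must be non-decreasing in units")

    def contraction_probability(self, units: int) -> float:
        z = self.contraction_intercept + self.contraction_slope * units
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class PrimerDesignRules:
    """Naive flank-primer picker (a deliberately crude Primer3 surrogate).

    Windows of ``primer_length`` bases with GC in [30, 60]% and Wallace-rule
    melting temperature 2(A+T) + 4(G+C) in [50, 70] degC are accepted;
    primers are positioned so the product length lands in
    [min_product, max_product], as close as feasible to ``opt_product``.
    """

    primer_length: int = 20
    gc_min: float = 30.0
    gc_max: float = 60.0
    tm_min: float = 50.0
    tm_max: float = 70.0
    min_product: int = 100
    max_product: int = 400
    opt_product: int = 250


@dataclass
class TruthRow:
    """Ground truth for one implanted locus across both genotypes."""

    locus_id: str
    seq_id: str
    motif: str
    canonical_motif: str
    period: int
    start_ref: int  # 1-based inclusive
    end_ref: int
    units_ref: int
    start_alt: int
    end_alt: int
    units_alt: int
    delta_units: int
    above_threshold: bool
    primer_forward: str | None = None
    primer_reverse: str | None = None
    product_ref: int | None = None
    product_alt: int | None = None

    @property
    def expected_class(self) -> str:
        if self.product_ref is None or self.product_alt is None:
            return "unresolved"
        return classify_polymorphism(self.product_ref, self.product_alt).value


@dataclass
class Fixture:
    """A complete in-memory synthetic study: two genotypes plus truth."""

    spec: GenomeSpec
    genome_ref: dict[str, str]
    genome_alt: dict[str, str]
    truth: list[TruthRow]

    @property
    def markers(self) -> list[TruthRow]:
        return [r for r in self.truth if r.primer_forward is not None]


class GenerationError(RuntimeError):
    pass


class PlacementError(ValueError):
    pass


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def generate_background(
    spec: GenomeSpec,
    scan_config: ScanConfig | None = None,
    max_passes: int = 60,
) -> dict[str, str]:
    """i.i.d. background at the target GC, free of threshold-passing SSRs.

    Each scaffold is scanned after generation; windows still harbouring a
    perfect repeat are re-sampled until the scaffold is clean (bounded
    number of passes, then GenerationError).
    """
    cfg = scan_config or ScanConfig()
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    for i in range(spec.n_scaffolds):
        seq_id = f"scaffold_{i + 1}"
        arr = _random_bases(rng, spec.scaffold_length, spec.gc)
        for _ in range(max_passes):
            seq = arr.tobytes().decode("ascii")
            loci = find_perfect_ssrs(seq, cfg, seq_id=seq_id)
            if not loci:
                break
            for l in loci:
                a, b = l.start - 1, l.end
                arr[a:b] = _random_bases(rng, b - a, spec.gc)
        else:
            raise GenerationError(f"{seq_id}: could not purge background repeats")
        genome[seq_id] = arr.tobytes().decode("ascii")
    return genome


def _weighted_choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def sample_implants(
    genome: Mapping[str, str],
    sampling: ImplantSampling,
    rng: np.random.Generator,
) -> list[Implant]:
    """Draw implant loci from the configured motif/unit distributions.

    Loci are laid out on a fixed spacing grid (so flanks stay repeat-free
    and wide enough for primer design) with the strand variant of each motif
    randomized among rotations of the motif and of its reverse complement.
    """
    slots: list[tuple[str, int]] = []
    for seq_id, seq in genome.items():
        pos = sampling.margin
        while pos + sampling.spacing < len(seq) - sampling.margin:
            slots.append((seq_id, pos))
            pos += sampling.spacing
    if sampling.n_loci > len(slots):
        raise PlacementError(
            f"{sampling.n_loci} loci requested but only {len(slots)} slots fit"
        )
    chosen = sorted(rng.choice(len(slots), size=sampling.n_loci, replace=False))
    implants: list[Implant] = []
    for slot_idx in chosen:
        seq_id, pos = slots[slot_idx]
        period = int(_weighted_choice(rng, sampling.period_weights))
        motif = str(_weighted_choice(rng, sampling.motif_weights[period]))
        # random strand/phase variant of the same canonical class
        rc = reverse_complement(motif)
        variants = [motif[i:] + motif[:i] for i in range(period)]
        variants += [rc[i:] + rc[:i] for i in range(period)]
        variant = variants[int(rng.integers(len(variants)))]
        units = sampling.min_units[period] + int(rng.geometric(sampling.unit_geom_p[period])) - 1
        units = min(units, sampling.max_units)
        implants.append(Implant(seq_id=seq_id, position=pos, motif=variant,
                                repeat_units=units))
    return implants


def _guard_base(rng: np.random.Generator, *avoid: str) -> str:
    options = [b for b in "ACGT" if b not in avoid]
    return options[int(rng.integers(len(options)))]


def implant_ssrs(
    genome: Mapping[str, str],
    implants: Sequence[Implant],
    scan_config: ScanConfig | None = None,
    rng: np.random.Generator | None = None,
    max_passes: int = 30,
    background_gc: float = 0.323,
) -> tuple[dict[str, str], list[TruthRow]]:
    """Write exact repeat tracts into the background and return ground truth.

    Each implant replaces background bases with ``repeat_units`` copies of
    its motif; the two immediately flanking bases are forced to break the
    repeat so the implanted tract is maximal exactly as specified.  The
    result is verified by re-scanning: recovered loci must equal the
    above-threshold truth rows (count, coordinates, motif, units); stray
    repeats created at junctions are re-sampled away.
    """
    cfg = scan_config or ScanConfig()
    rng = rng if rng is not None else np.random.default_rng(0)

    by_scaffold: dict[str, list[Implant]] = {}
    for imp in implants:
        if imp.seq_id not in genome:
            raise PlacementError(f"unknown scaffold {imp.seq_id}")
        L = len(imp.motif) * imp.repeat_units
        if imp.position < 1 or imp.position + L + 1 > len(genome[imp.seq_id]):
            raise PlacementError(f"implant out of range: {imp}")
        by_scaffold.setdefault(imp.seq_id, []).append(imp)

    for seq_id, imps in by_scaffold.items():
        imps.sort(key=lambda x: x.position)
        for a, b in zip(imps, imps[1:]):
            if a.position + len(a.motif) * a.repeat_units + 1 >= b.position:
                raise PlacementError(f"overlapping implants on {seq_id}: {a} / {b}")

    out: dict[str, str] = dict(genome)
    rows: list[TruthRow] = []
    counter = 0
    for seq_id, seq in genome.items():
        imps = by_scaffold.get(seq_id, [])
        arr = bytearray(seq, "ascii")
        for imp in imps:
            p = len(imp.motif)
            L = p * imp.repeat_units
            a = imp.position
            tract = (imp.motif * imp.repeat_units).encode("ascii")
            arr[a : a + L] = tract
            # guards: left base must not extend the repeat by one base; same
            # on the right (keeps the truth coordinates exactly maximal)
            arr[a - 1] = ord(_guard_base(rng, imp.motif[p - 1]))
            arr[a + L] = ord(_guard_base(rng, imp.motif[0]))
            counter += 1
            above = (
                imp.repeat_units >= cfg.min_repeat_units
                and cfg.min_period <= p <= cfg.max_period
                and L >= cfg.min_length(p)
            )
            rows.append(
                TruthRow(
                    locus_id=f"L{counter:05d}",
                    seq_id=seq_id,
                    motif=imp.motif,
                    canonical_motif=canonical_motif(imp.motif),
                    period=p,
                    start_ref=a + 1,
                    end_ref=a + L,
                    units_ref=imp.repeat_units,
                    start_alt=a + 1,
                    end_alt=a + L,
                    units_alt=imp.repeat_units,
                    delta_units=0,
                    above_threshold=above,
                )
            )

        # verification pass: the scan must recover exactly the implants
        expected = {
            (r.start_ref, r.end_ref, r.motif, r.units_ref)
            for r in rows
            if r.seq_id == seq_id and r.above_threshold
        }
        # 0-based spans covering each tract plus its two guard bases
        implant_spans = [(r.start_ref - 2, r.end_ref + 1) for r in rows if r.seq_id == seq_id]

        def _inside_implant(x: int) -> bool:
            return any(s <= x < e for s, e in implant_spans)

        ok = False
        for _ in range(max_passes):
            found = {
                (l.start, l.end, l.motif, l.repeat_units)
                for l in find_perfect_ssrs(arr.decode("ascii"), cfg, seq_id=seq_id)
            }
            stray = found - expected
            if not stray and expected <= found:
                ok = True
                break
            for s, e, _, _ in stray:
                for x in range(s - 1, e):
                    if not _inside_implant(x):
                        arr[x] = int(_random_bases(rng, 1, background_gc)[0])
        if not ok:
            raise GenerationError(f"{seq_id}: implant verification failed")
        out[seq_id] = arr.decode("ascii")
    rows.sort(key=lambda r: (r.seq_id, r.start_ref))
    return out, rows


def mutate_genotype(
    genome: Mapping[str, str],
    truth: Sequence[TruthRow],
    model: MutationModel,
    seed: int,
) -> tuple[dict[str, str], list[TruthRow]]:
    """Derive the alternate genotype by repeat-unit slippage at truth loci.

    Flanking sequence is untouched; only the tract lengths change, so the
    alternate coordinates of each locus shift by the cumulative unit changes
    upstream on the same scaffold.  Returns the new genome and updated truth
    rows (both alleles and the signed unit change recorded).
    """
    rng = np.random.default_rng(seed)
    out_genome: dict[str, str] = {}
    out_rows: list[TruthRow] = []
    rows_by_scaffold: dict[str, list[TruthRow]] = {}
    for r in sorted(truth, key=lambda r: (r.seq_id, r.start_ref)):
        rows_by_scaffold.setdefault(r.seq_id, []).append(r)

    for seq_id, seq in genome.items():
        pieces: list[str] = []
        cursor = 0  # 0-based position in the reference scaffold
        offset = 0  # alt minus ref coordinate shift so far
        for r in rows_by_scaffold.get(seq_id, []):
            units_alt = r.units_ref
            if rng.random() < model.p_change:
                p_con = model.contraction_probability(r.units_ref)
                contraction = rng.random() < p_con
                step = int(rng.geometric(model.step_geom_p))
                if contraction:
                    # resample steps that would leave fewer than one unit
                    for _ in range(100):
                        if r.units_ref - step >= 1:
                            break
                        step = int(rng.geometric(model.step_geom_p))
                    else:
                        step = max(r.units_ref - 1, 0)
                    if step == 0:  # a single-unit locus cannot contract
                        contraction = False
                        step = int(rng.geometric(model.step_geom_p))
                units_alt = r.units_ref + (-step if contraction else step)
            a = r.start_ref - 1
            pieces.append(seq[cursor:a])
            pieces.append(r.motif * units_alt)
            cursor = r.end_ref
            start_alt = a + offset + 1
            delta = units_alt - r.units_ref
            out_rows.append(
                TruthRow(
                    **{
                        **asdict(r),
                        "units_alt": units_alt,
                        "start_alt": start_alt,
                        "end_alt": start_alt + r.period * units_alt - 1,
                        "delta_units": delta,
                    }
                )
            )
            offset += delta * r.period
        pieces.append(seq[cursor:])
        out_genome[seq_id] = "".join(pieces)
    out_rows.sort(key=lambda r: (r.seq_id, r.start_ref))
    return out_genome, out_rows


def _window_ok(window: str, rules: PrimerDesignRules) -> bool:
    gc = window.count("G") + window.count("C")
    at = window.count("A") + window.count("T")
    if gc + at != len(window):
        return False
    gc_pct = 100.0 * gc / len(window)
    tm = 2.0 * at + 4.0 * gc
    return rules.gc_min <= gc_pct <= rules.gc_max and rules.tm_min <= tm <= rules.tm_max


def design_flank_primers(
    sequence: str,
    start: int,
    end: int,
    rules: PrimerDesignRules | None = None,
) -> tuple[str, str, int] | None:
    """Pick a flanking primer pair around a locus (1-based closed coords).

    Returns (forward, reverse, product_length) with the reverse primer given
    5'->3' on the opposite strand, or None when no feasible windows exist.
    The search expands symmetrically from the pad that would give the
    optimum product, taking the first feasible window on each side, which
    makes the choice deterministic.
    """
    rules = rules or PrimerDesignRules()
    Lp = rules.primer_length
    a = start - 1          # 0-based tract start
    b = end                # 0-based exclusive tract end
    locus_len = b - a
    pad0 = max(0, (rules.opt_product - locus_len - 2 * Lp) // 2)
    max_pad = (rules.max_product - locus_len - 2 * Lp)

    def _probe(side: str) -> tuple[int, str] | None:
        for delta in range(0, max(max_pad, pad0) + 1):
            for pad in (pad0 + delta, pad0 - delta) if delta else (pad0,):
                if pad < 0 or pad > max_pad:
                    continue
                if side == "left":
                    ls = a - pad - Lp
                    if ls < 0:
                        continue
                    win = sequence[ls : ls + Lp]
                else:
                    rs = b + pad
                    if rs + Lp > len(sequence):
                        continue
                    win = sequence[rs : rs + Lp]
                if _window_ok(win, rules):
                    return (ls, win) if side == "left" else (rs, win)
        return None

    left = _probe("left")
    right = _probe("right")
    if left is None or right is None:
        return None
    ls, fwd = left
    rs, rwin = right
    product = (rs + Lp) - ls
    if not (rules.min_product <= product <= rules.max_product):
        return None
    return fwd, reverse_complement(rwin), product


def build_fixture(
    seed: int = 0,
    spec: GenomeSpec | None = None,
    sampling: ImplantSampling | None = None,
    model: MutationModel | None = None,
    scan_config: ScanConfig | None = None,
    primer_rules: PrimerDesignRules | None = None,
) -> Fixture:
    """Generate a complete two-genotype study: the main entry point.

    Deterministic given (seed, specs).  The genome spec's own seed is
    derived from ``seed`` unless an explicit spec is supplied.
    """
    spec = spec or GenomeSpec(seed=seed)
    sampling = sampling or ImplantSampling()
    model = model or MutationModel()
    cfg = scan_config or ScanConfig()
    primer_rules = primer_rules or PrimerDesignRules()

    rng = np.random.default_rng(seed + 1)
    background = generate_background(spec, cfg)
    implants = sample_implants(background, sampling, rng)
    genome_ref, truth = implant_ssrs(background, implants, cfg, rng,
                                     background_gc=spec.gc)
    genome_alt, truth = mutate_genotype(genome_ref, truth, model, seed + 2)

    markers = 0
    for r in truth:
        picked = design_flank_primers(
            genome_ref[r.seq_id], r.start_ref, r.end_ref, primer_rules
        )
        if picked is None:
            continue
        fwd, rev, product = picked
        markers += 1
        r.primer_forward = fwd
        r.primer_reverse = rev
        r.product_ref = product
        r.product_alt = product + r.delta_units * r.period
    return Fixture(spec=spec, genome_ref=genome_ref, genome_alt=genome_alt,
                   truth=truth)


def _write_fasta(path: Path, genome: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in genome.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def emit_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture to disk: FASTA x2, primer TSV, truth TSV, config.

    Re-running with the same fixture reproduces byte-identical files.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_ref": outdir / "genotype_ref.fasta",
        "genome_alt": outdir / "genotype_alt.fasta",
        "primers": outdir / "primers.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    _write_fasta(paths["genome_ref"], fixture.genome_ref)
    _write_fasta(paths["genome_alt"], fixture.genome_alt)

    truth_df = pd.DataFrame([
        {**asdict(r), "expected_class": r.expected_class} for r in fixture.truth
    ])
    truth_df.to_csv(paths["truth"], sep="\t", index=False)

    primer_df = pd.DataFrame(
        [
            {
                "marker_id": r.locus_id,
                "forward": r.primer_forward,
                "reverse": r.primer_reverse,
                "expected_size": r.product_ref,
                "expected_motif": r.canonical_motif,
            }
            for r in fixture.markers
        ]
    )
    primer_df.to_csv(paths["primers"], sep="\t", index=False)

    cfg = {"spec": asdict(fixture.spec), "n_loci": len(fixture.truth),
           "n_markers": len(fixture.markers)}
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths


def fixture_checksums(fixture: Fixture) -> dict[str, str]:
    """Stable content digests, handy for determinism checks."""
    h = {}
    for name, genome in (("ref", fixture.genome_ref), ("alt", fixture.genome_alt)):
        m = hashlib.sha256()
        for seq_id in sorted(genome):
            m.update(seq_id.encode())
            m.update(genome[seq_id].encode())
        h[name] = m.hexdigest()
    return h
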