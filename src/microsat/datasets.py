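"""Published survey values used as worked-example inputs.

These constants transcribe the headline numbers of the genome-wide
microsatellite survey of the cucumber 'Gy14' assembly (and its companion
comparison of eight plant species) that this package re-implements.  They
are *inputs* for arithmetic and statistical reproduction — counts, assembly
sizes and per-species densities as printed — never outputs of this package.
"""

from __future__ import annotations

#: Assembled Gy14 sequence analysed (bp).
GY14_ASSEMBLY_BP: int = 203_052_159

#: Perfect SSR counts in the Gy14 assembly by motif period (di- to octa-).
GY14_GENOMIC_COUNTS: dict[int, int] = {
    2: 29_651,
    3: 28_645,
    4: 33_348,
    5: 11_038,
    6: 6_290,
    7: 2_337,
    8: 764,
}

#: Mean repeat number (complete units) by period in the Gy14 assembly.
GY14_MEAN_REPEAT_NUMBER: dict[int, float] = {
    2: 9.6, 3: 4.9, 4: 3.2, 5: 3.2, 6: 3.3, 7: 3.3, 8: 3.2,
}

#: Dinucleotide SSR density (SSR/Mbp) in genomic sequence for the eight
#: species surveyed: cucumber, Medicago, soybean, poplar, Arabidopsis,
#: grapevine, rice, sorghum.
DINUCLEOTIDE_GENOMIC_DENSITIES: tuple[float, ...] = (
    146.0, 61.5, 74.6, 132.6, 78.7, 117.2, 100.1, 51.6,
)

#: Matching dinucleotide densities in the clustered-EST (transcript) data of
#: the same eight species.
DINUCLEOTIDE_EST_DENSITIES: tuple[float, ...] = (
    75.0, 36.6, 81.1, 86.6, 47.8, 40.7, 57.9, 52.1,
)

#: Marker-panel outcome of the two-genotype (Gy14 vs 9930) comparison:
#: of 2,099 primer pairs screened, 1,542 produced specific products; 407
#: were unresolved (paired-end contigs), 129 differed by exactly 1 bp
#: (ambiguous), leaving 1,006 classifiable loci.
MARKER_PANEL_COUNTS: dict[str, int] = {
    "screened": 2_099,
    "specific": 1_542,
    "unresolved": 407,
    "ambiguous": 129,
    "monomorphic": 520,
    "polymorphic": 486,
}

#: Counts of classifiable loci by polymorphism class, motif period and
#: reference repeat-tract length bin (<30 nt, 30-40 nt, >40 nt).
#: Heterogeneous compound loci (25) are excluded, hence 514 + 467 = 981.
REPEAT_LENGTH_TABLE: dict[str, dict[int, tuple[int, int, int]]] = {
    "monomorphic": {
        2: (34, 29, 13),
        3: (95, 119, 63),
        4: (26, 38, 10),
        5: (0, 33, 10),
        6: (1, 32, 11),
    },
    "polymorphic": {
        2: (42, 102, 75),
        3: (21, 67, 49),
        4: (21, 24, 13),
        5: (0, 18, 3),
        6: (0, 15, 17),
    },
}
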