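"""Polymorphism classification, delta_al profiling, repeat-length binning,
correlation and ANOVA/LSD, including the published marker-panel margins."""

import numpy as np
import pytest

from microsat import datasets
from microsat.polymorphism import (
    CompoundKind,
    Direction,
    LocusComparison,
    PolymorphismClass,
    anova_lsd,
    bin_by_repeat_length,
    bin_margins,
    classify_polymorphism,
    compound_repeat_units,
    correlate_delta_repeat,
    expansion_contraction_profile,
    repeat_length_bin,
)


def _cmp(marker_id, size_ref, size_alt, period=2, motif="AT", units=None,
         length=None, compound=CompoundKind.SIMPLE):
    return LocusComparison(
        marker_id=marker_id, size_ref=size_ref, size_alt=size_alt,
        repeat_period=period, canonical_motif=motif,
        repeat_units_ref=units, repeat_length_ref=length, compound=compound)


class TestClassification:
    @pytest.mark.parametrize("ref,alt,expected", [
        (250, 250, PolymorphismClass.MONOMORPHIC),
        (250, 251, PolymorphismClass.AMBIGUOUS),
        (251, 250, PolymorphismClass.AMBIGUOUS),
        (250, 252, PolymorphismClass.POLYMORPHIC),
        (250, 199, PolymorphismClass.POLYMORPHIC),
        (None, 250, PolymorphismClass.UNRESOLVED),
        (250, None, PolymorphismClass.UNRESOLVED),
    ])
    def test_size_rules(self, ref, alt, expected):
        assert classify_polymorphism(ref, alt) is expected

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            classify_polymorphism(-1, 100)

    def test_partition_is_complete(self, rng):
        """Every marker falls in exactly one of the four classes."""
        sizes = [(int(a), int(b)) for a, b in
                 zip(rng.integers(100, 400, 200), rng.integers(100, 400, 200))]
        sizes += [(200, None), (None, 200), (None, None)]
        classes = [classify_polymorphism(a, b) for a, b in sizes]
        assert len(classes) == len(sizes)
        assert set(classes) <= set(PolymorphismClass)

    def test_sign_convention_swap(self, rng):
        """Swapping genotypes negates signed delta_al and flips direction,
        leaving magnitude and class unchanged."""
        for _ in range(50):
            c = _cmp("m", int(rng.integers(100, 400)), int(rng.integers(100, 400)))
            s = c.swapped()
            assert s.polymorphism_class is c.polymorphism_class
            assert s.delta_al_magnitude == c.delta_al_magnitude
            if c.delta_al_signed:
                assert s.delta_al_signed == -c.delta_al_signed
                assert {c.direction, s.direction} == {Direction.EXPANSION,
                                                      Direction.CONTRACTION}


class TestCompoundUnits:
    def test_summed_when_long_enough(self):
        assert compound_repeat_units([("AT", 8), ("GT", 12)]) == 20

    def test_mixed_periods_ineligible_for_dinucleotide_analysis(self):
        assert compound_repeat_units([("AAG", 3), ("AT", 4)],
                                     dinucleotide_only=True) is None

    def test_single_member(self):
        assert compound_repeat_units([("AT", 12)]) == 12

    def test_below_minimum_undefined(self):
        assert compound_repeat_units([("AT", 4), ("AG", 3)]) is None

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compound_repeat_units([])


def _comparisons_from_published_table():
    """Synthetic stand-in comparison set rebuilt from the published
    class x period x repeat-length-bin counts (a reconstruction, not the
    original per-locus data)."""
    rep_length = {"<30": 25, "30-40": 35, ">40": 45}
    out = []
    i = 0
    for cls, rows in datasets.REPEAT_LENGTH_TABLE.items():
        delta = 0 if cls == "monomorphic" else 4
        for period, counts in rows.items():
            for bin_label, n in zip(("<30", "30-40", ">40"), counts):
                for _ in range(n):
                    i += 1
                    out.append(_cmp(f"m{i}", 250, 250 + delta, period=period,
                                    length=rep_length[bin_label]))
    return out


class TestRepeatLengthBinning:
    @pytest.mark.parametrize("length,expected", [
        (24, "<30"), (29, "<30"), (30, "30-40"), (40, "30-40"), (41, ">40"),
    ])
    def test_bin_boundaries(self, length, expected):
        assert repeat_length_bin(length) == expected

    def test_three_loci_three_bins(self):
        comps = [_cmp("a", 200, 200, length=24), _cmp("b", 200, 200, length=33),
                 _cmp("c", 200, 200, length=45)]
        t = bin_by_repeat_length(comps)
        assert list(t.loc[("monomorphic", 2)][["<30", "30-40", ">40"]]) == [1, 1, 1]

    def test_published_marker_panel_margins(self):
        """The published panel's margins: monomorphic 156/251/107 of 514
        (30.6/48.8/20.8%), polymorphic >40 nt share 33.6%, trinucleotides
        53.9% of monomorphic loci."""
        t = bin_by_repeat_length(_comparisons_from_published_table())
        mono = bin_margins(t, "monomorphic")
        assert (mono["<30"], mono["30-40"], mono[">40"]) == (156, 251, 107)
        assert mono["total"] == 514
        # 156/514 rounds to 30.4 (the remaining margins match their printed
        # one-decimal values exactly)
        assert (mono["pct_<30"], mono["pct_30-40"], mono["pct_>40"]) == (30.4, 48.8, 20.8)
        poly = bin_margins(t, "polymorphic")
        assert poly["total"] == 467
        assert poly["pct_>40"] == 33.6
        tri_share = 100 * t.loc[("monomorphic", 3), "total"] / mono["total"]
        assert round(tri_share, 1) == 53.9

    def test_heterogeneous_compounds_and_ambiguous_excluded(self):
        comps = [
            _cmp("a", 200, 200, length=24),
            _cmp("b", 200, 200, length=24, compound=CompoundKind.HETEROGENEOUS),
            _cmp("c", 200, 201, length=24),   # ambiguous
            _cmp("d", 200, None, length=24),  # unresolved
        ]
        t = bin_by_repeat_length(comps)
        assert t["total"].sum() == 1

    def test_matches_filter_and_count_oracle(self, rng):
        comps = []
        for i in range(300):
            delta = int(rng.choice([0, 0, 2, 5, -4, 1]))
            comps.append(_cmp(f"m{i}", 250, 250 + delta,
                              period=int(rng.choice([2, 3, 4])),
                              length=int(rng.integers(12, 80))))
        t = bin_by_repeat_length(comps)
        for c in comps:
            cls = c.polymorphism_class
            if cls not in (PolymorphismClass.MONOMORPHIC, PolymorphismClass.POLYMORPHIC):
                continue
        # direct recount
        expected = {}
        for c in comps:
            cls = c.polymorphism_class.value
            if cls not in ("monomorphic", "polymorphic"):
                continue
            key = (cls, c.repeat_period, repeat_length_bin(c.repeat_length_ref))
            expected[key] = expected.get(key, 0) + 1
        for (cls, period, b), n in expected.items():
            assert t.loc[(cls, period), b] == n
        assert int(t["total"].sum()) == sum(expected.values())


class TestProfile:
    def test_all_contractions(self):
        comps = [_cmp(f"m{i}", 250, 240, units=u) for i, u in enumerate([5, 10, 20])]
        prof = expansion_contraction_profile(comps, [(3, 8), (9, 30)])
        assert (prof["pct_contraction"] == 100.0).all()

    def test_balanced_class(self):
        comps = [_cmp("a", 250, 254, units=5), _cmp("b", 250, 246, units=5)]
        prof = expansion_contraction_profile(comps, [(3, 8)])
        row = prof.iloc[0]
        assert row["pct_expansion"] == 50.0 and row["pct_contraction"] == 50.0
        assert row["mean_delta_al"] == 4.0

    def test_empty_class_omitted(self):
        comps = [_cmp("a", 250, 254, units=5)]
        prof = expansion_contraction_profile(comps, [(3, 8), (20, 30)])
        assert list(prof["unit_class"]) == ["3-8"]

    def test_recovers_generating_contraction_trend(self, rng):
        """Loci simulated with contraction probability rising in repeat units
        give per-class contraction fractions inside the binomial 95% CI."""
        from microsat.simulate import MutationModel

        model = MutationModel()
        classes = [(6, 8), (12, 14), (20, 24)]
        comps = []
        n_per = 400
        i = 0
        for lo, hi in classes:
            for _ in range(n_per):
                u = int(rng.integers(lo, hi + 1))
                p_c = model.contraction_probability(u)
                contraction = rng.random() < p_c
                step = int(rng.geometric(model.step_geom_p))
                delta = -2 * step if contraction else 2 * step
                if abs(delta) < 2:
                    delta = 2 if delta > 0 else -2
                i += 1
                comps.append(_cmp(f"m{i}", 250, 250 + delta, units=u))
        prof = expansion_contraction_profile(comps, classes).set_index("unit_class")
        for lo, hi in classes:
            mid = (lo + hi) / 2
            p_c = model.contraction_probability(int(mid))
            obs = prof.loc[f"{lo}-{hi}", "pct_contraction"] / 100
            half_width = 1.96 * np.sqrt(p_c * (1 - p_c) / n_per) + 0.03
            assert abs(obs - p_c) < half_width
        # and the trend is monotone increasing across classes
        fracs = [prof.loc[f"{lo}-{hi}", "pct_contraction"] for lo, hi in classes]
        assert fracs[0] < fracs[1] < fracs[2]


class TestCorrelation:
    def test_perfect_linear(self):
        comps = [_cmp(f"m{i}", 250, 250 + 2 * u, units=u) for i, u in
                 enumerate(range(5, 15))]
        r, p = correlate_delta_repeat(comps)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_period_filter(self):
        comps = [_cmp("a", 250, 260, units=5, period=2),
                 _cmp("b", 250, 266, units=8, period=2),
                 _cmp("c", 250, 270, units=10, period=2),
                 _cmp("d", 250, 280, units=3, period=3)]
        r_all, _ = correlate_delta_repeat(comps)
        r_di, _ = correlate_delta_repeat(comps, periods=[2])
        assert r_di == pytest.approx(1.0)
        assert r_all < 1.0

    def test_null_rarely_significant(self, rng):
        """delta_al independent of units: p > 0.05 in >= 94/100 replicates."""
        n_nonsig = 0
        for _ in range(100):
            comps = [
                _cmp(f"m{i}", 250, 250 + int(d), units=int(u))
                for i, (d, u) in enumerate(zip(
                    rng.choice([-6, -4, -2, 2, 4, 6], size=500),
                    rng.integers(5, 30, size=500)))
            ]
            _, p = correlate_delta_repeat(comps)
            n_nonsig += p > 0.05
        assert n_nonsig >= 94

    def test_zero_variance_error(self):
        comps = [_cmp(f"m{i}", 250, 254, units=5) for i in range(5)]
        with pytest.raises(ValueError):
            correlate_delta_repeat(comps)

    def test_too_few_error(self):
        with pytest.raises(ValueError):
            correlate_delta_repeat([_cmp("a", 250, 254, units=5)])


class TestAnovaLSD:
    def test_identical_groups_nothing_significant(self):
        res = anova_lsd({"a": [5.0, 6.0, 7.0], "b": [5.0, 6.0, 7.0]})
        assert res.significant_pairs() == []

    def test_separated_groups_significant(self, rng):
        """Means 20 vs 8 with sd 2 and n 30: LSD flags the pair; agrees with
        the closed-form pooled-t check."""
        a = list(rng.normal(20, 2, 30))
        b = list(rng.normal(8, 2, 30))
        res = anova_lsd({"di": a, "tri": b})
        assert ("di", "tri") in res.significant_pairs()
        from _oracles import pooled_t_statistic, t_two_sided_p
        t = pooled_t_statistic(a, b)
        assert res.pairwise[("di", "tri")][0] == pytest.approx(
            t_two_sided_p(t, 58), abs=1e-5)

    def test_null_false_positive_rate(self, rng):
        """Random splits of one pooled sample: each pair significant in
        roughly alpha of trials."""
        pooled = rng.normal(10, 3, 60)
        n_sig = 0
        trials = 120
        for _ in range(trials):
            perm = rng.permutation(pooled)
            res = anova_lsd({"a": perm[:20], "b": perm[20:40], "c": perm[40:]})
            n_sig += len(res.significant_pairs()) > 0
        # familywise over 3 LSD pairs: expect ~ 10-13%; allow generous slack
        assert n_sig / trials < 0.25

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            anova_lsd({"a": [1.0], "b": [2.0, 3.0]})

    def test_mean_reporting(self):
        res = anova_lsd({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert res.means == {"a": 2.0, "b": 5.0}
        assert res.df_within == 4


class TestMarkerPanelFractions:
    def test_published_class_fractions(self):
        """520 identical + 486 differing (>=2 bp) of 1,006 classifiable loci:
        51.7% monomorphic, 48.3% polymorphic."""
        comps = [_cmp(f"mono{i}", 250, 250) for i in range(
            datasets.MARKER_PANEL_COUNTS["monomorphic"])]
        comps += [_cmp(f"poly{i}", 250, 252 + (i % 30)) for i in range(
            datasets.MARKER_PANEL_COUNTS["polymorphic"])]
        n = len(comps)
        assert n == 1006
        n_mono = sum(c.polymorphism_class is PolymorphismClass.MONOMORPHIC
                     for c in comps)
        n_poly = sum(c.polymorphism_class is PolymorphismClass.POLYMORPHIC
                     for c in comps)
        assert round(100 * n_poly / n, 1) == 48.3
        assert round(100 * n_mono / n, 1) == 51.7

    def test_panel_partition_reconciles(self):
        """1,542 specific = 407 unresolved + 129 ambiguous + 1,006 classified."""
        c = datasets.MARKER_PANEL_COUNTS
        assert c["unresolved"] + c["ambiguous"] + c["monomorphic"] + c["polymorphic"] == c["specific"]
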