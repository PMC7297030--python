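"""Exact expectations for the phase-resolved marker segregation types."""

from fractions import Fraction
from itertools import product

import pytest

from afddmap import (
    ALL_DERIVATIVES,
    MarkerSegregation,
    RecessiveModel,
    enumerate_offspring,
    expectation_table,
    expected_pool_af,
    informative_filter_windows,
)
from afddmap.segregation import ConfigurationError, pool_af_from_enumeration


def brute_force_pool_af(seg: MarkerSegregation, n_loci: int):
    """Independent oracle: exhaustive product over per-parent gametes.

    Each gamete fixes the transmitted haplotype at the marker chromosome and,
    for the two-locus model, the allele at the unlinked second locus; all
    combinations are equally likely.
    """

    def gametes(pair):
        # (marker allele, locus1 recessive?, locus2 recessive?)
        for hap in (0, 1):
            for l2 in ((True, False) if n_loci == 2 else (None,)):
                yield (pair[hap], hap == 0, l2)

    rec_dose = rec_n = dom_dose = dom_n = 0
    for g1, g2 in product(gametes(seg.seed_parent), gametes(seg.pollen_parent)):
        dose = (g1[0] == "V") + (g2[0] == "V")
        recessive = g1[1] and g2[1] and (n_loci == 1 or (g1[2] and g2[2]))
        if recessive:
            rec_dose += dose
            rec_n += 1
        else:
            dom_dose += dose
            dom_n += 1
    af_rec = Fraction(100 * rec_dose, 2 * rec_n)
    af_dom = Fraction(100 * dom_dose, 2 * dom_n)
    return af_rec, af_dom


class TestLabels:
    def test_named_types_round_trip(self):
        for label in "ABCDE":
            assert MarkerSegregation.from_label(label).label == label

    def test_type_configurations(self):
        assert MarkerSegregation(("V", "R"), ("V", "R")).label == "A"
        assert MarkerSegregation(("V", "R"), ("V", "V")).label == "B"
        assert MarkerSegregation(("V", "V"), ("V", "R")).label == "C"
        assert MarkerSegregation(("V", "R"), ("R", "R")).label == "D"
        assert MarkerSegregation(("R", "R"), ("V", "R")).label == "E"
        assert MarkerSegregation(("R", "V"), ("R", "V")).label == "other"

    def test_twelve_derivatives(self):
        assert len(ALL_DERIVATIVES) == 12
        assert len({(s.seed_parent, s.pollen_parent) for s in ALL_DERIVATIVES}) == 12

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            MarkerSegregation(("V",), ("V", "R"))
        with pytest.raises(ConfigurationError):
            MarkerSegregation(("V", "X"), ("V", "R"))
        with pytest.raises(ConfigurationError):
            RecessiveModel(3)
        with pytest.raises(ConfigurationError):
            MarkerSegregation.from_label("Z")


class TestEnumeration:
    def test_type_a_mendelian_marginal(self):
        dist = enumerate_offspring(MarkerSegregation.from_label("A"), RecessiveModel(1))
        marginal = {}
        for (gt, _klass), p in dist.items():
            marginal[gt] = marginal.get(gt, Fraction(0)) + p
        assert marginal == {
            "VV": Fraction(1, 4), "VR": Fraction(1, 2), "RR": Fraction(1, 4)
        }
        assert sum(dist.values()) == 1

    def test_type_a_recessive_class_homozygous_variant(self):
        dist = enumerate_offspring(MarkerSegregation.from_label("A"), RecessiveModel(1))
        rec = {gt: p for (gt, k), p in dist.items() if k == "recessive"}
        assert sum(rec.values()) == Fraction(1, 4)
        assert set(rec) == {"VV"}

    def test_type_d_two_gene_recessives_are_het(self):
        dist = enumerate_offspring(MarkerSegregation.from_label("D"), RecessiveModel(2))
        rec = {gt: p for (gt, k), p in dist.items() if k == "recessive"}
        assert sum(rec.values()) == Fraction(1, 16)
        assert set(rec) == {"VR"}

    @pytest.mark.parametrize("n_loci", [1, 2])
    def test_recessive_probability(self, n_loci):
        for seg in ALL_DERIVATIVES:
            dist = enumerate_offspring(seg, RecessiveModel(n_loci))
            p_rec = sum(p for (_gt, k), p in dist.items() if k == "recessive")
            assert p_rec == Fraction(1, 4) ** n_loci


PRINTED = [
    # label, n_loci, af_rec, af_dom, afdd (exact rationals behind the
    # printed one-decimal values 33.3/46.7/66.7/73.3/16.7/23.3 ...)
    ("A", 1, Fraction(100), Fraction(100, 3), Fraction(200, 3)),
    ("A", 2, Fraction(100), Fraction(140, 3), Fraction(160, 3)),
    ("B", 1, Fraction(100), Fraction(200, 3), Fraction(100, 3)),
    ("B", 2, Fraction(100), Fraction(220, 3), Fraction(80, 3)),
    ("C", 1, Fraction(100), Fraction(200, 3), Fraction(100, 3)),
    ("C", 2, Fraction(100), Fraction(220, 3), Fraction(80, 3)),
    ("D", 1, Fraction(50), Fraction(50, 3), Fraction(100, 3)),
    ("D", 2, Fraction(50), Fraction(70, 3), Fraction(80, 3)),
    ("E", 1, Fraction(50), Fraction(50, 3), Fraction(100, 3)),
    ("E", 2, Fraction(50), Fraction(70, 3), Fraction(80, 3)),
]


class TestExpectedPoolAF:
    @pytest.mark.parametrize("label,n_loci,af_rec,af_dom,afdd", PRINTED)
    def test_published_values_exact(self, label, n_loci, af_rec, af_dom, afdd):
        exp = expected_pool_af(MarkerSegregation.from_label(label), n_loci)
        assert exp.af_recessive_pool == af_rec
        assert exp.af_dominant_pool == af_dom
        assert exp.afdd == afdd
        assert exp.informative

    @pytest.mark.parametrize("n_loci", [1, 2])
    def test_all_derivatives_match_brute_force(self, n_loci):
        for seg in ALL_DERIVATIVES:
            exp = expected_pool_af(seg, n_loci)
            af_rec, af_dom = brute_force_pool_af(seg, n_loci)
            assert exp.af_recessive_pool == af_rec, seg
            assert exp.af_dominant_pool == af_dom, seg

    @pytest.mark.parametrize("n_loci", [1, 2])
    def test_closed_form_matches_package_enumeration_route(self, n_loci):
        for seg in ALL_DERIVATIVES:
            a = expected_pool_af(seg, n_loci)
            b = pool_af_from_enumeration(seg, n_loci)
            assert (a.af_recessive_pool, a.af_dominant_pool) == (
                b.af_recessive_pool, b.af_dominant_pool
            )

    def test_exactly_five_informative(self):
        for n_loci in (1, 2):
            informative = [
                s for s in ALL_DERIVATIVES
                if expected_pool_af(s, n_loci).informative
            ]
            assert sorted(s.label for s in informative) == list("ABCDE")

    def test_afdd_ordering(self):
        for n_loci in (1, 2):
            afdd = {
                lbl: expected_pool_af(MarkerSegregation.from_label(lbl), n_loci).afdd
                for lbl in "ABCDE"
            }
            assert afdd["A"] > afdd["B"] == afdd["C"] == afdd["D"] == afdd["E"]
        for lbl in "ABCDE":
            one = expected_pool_af(MarkerSegregation.from_label(lbl), 1).afdd
            two = expected_pool_af(MarkerSegregation.from_label(lbl), 2).afdd
            assert two < one

    def test_repulsion_configuration_not_informative(self):
        exp = expected_pool_af(MarkerSegregation(("R", "V"), ("R", "V")), 1)
        assert exp.afdd <= 0 and not exp.informative


class TestFilterWindows:
    def test_published_bounds(self):
        a, bc, de = informative_filter_windows({1, 2})
        assert (a.af_recessive_min, a.afdd_min) == (85.0, 43.3)
        assert (bc.af_recessive_min, bc.afdd_min, bc.afdd_max) == (85.0, 16.7, 43.3)
        assert (de.af_recessive_min, de.af_recessive_max) == (35.0, 65.0)
        assert (de.afdd_min, de.afdd_max) == (16.7, 43.3)

    def test_boundary_semantics(self):
        a, bc, de = informative_filter_windows()
        # AFDD exactly 43.3 belongs to A, not B/C (half-open upper bound)
        assert a.contains(90.0, 43.3) and not bc.contains(90.0, 43.3)
        assert bc.contains(90.0, 16.7)
        assert de.contains(35.0, 43.3) and de.contains(65.0, 16.7)
        assert not de.contains(34.9, 30.0)

    def test_bounds_constant_for_single_model(self):
        assert informative_filter_windows({1}) == informative_filter_windows({1, 2})
        with pytest.raises(ConfigurationError):
            informative_filter_windows(set())


def test_expectation_table_shape_and_content():
    table = expectation_table()
    assert len(table) == 24
    assert table["informative"].sum() == 10
    a1 = table[(table.label == "A") & (table.n_loci == 1)].iloc[0]
    assert round(a1.af_dominant, 1) == 33.3
    assert round(a1.afdd, 1) == 66.7
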