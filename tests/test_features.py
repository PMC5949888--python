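"""Peptide feature framework: catalog, compositions, motifs, scalars, stats."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadscreen import features as ft
from tadscreen.features.encodings import (
    AA_GROUPS,
    AA_ORDER,
    MINIMOTIF_GROUPS,
    PKA_CTERM,
    PKA_NTERM,
)
from tadscreen.seqs import InvalidAlphabetError

from conftest import count_minimotif_pairs, exact_mannwhitney_p

PEPTIDES = st.text(alphabet=sorted(AA_ORDER), min_size=1, max_size=30)


class TestCatalog:
    def test_exactly_146_features_with_unique_ids(self):
        catalog = ft.build_default_catalog()
        ids = [d.feature_id for d in catalog]
        assert len(catalog) == 146
        assert len(set(ids)) == 146

    def test_all_eight_feature_sets_present(self):
        catalog = ft.build_default_catalog()
        sets = {d.feature_set for d in catalog}
        assert sets == {
            "aa_composition", "group_composition", "minimotif", "ninetad",
            "disorder", "helicity", "general", "pi",
        }

    def test_legacy_features_always_present(self):
        ids = {d.feature_id for d in ft.build_default_catalog()}
        assert set(ft.FORCED_KEEP_FEATURES) <= ids

    def test_bundled_file_matches_programmatic_definitions(self):
        assert ft.build_default_catalog() == ft.default_catalog_definitions()


class TestComputeFeature:
    def test_membership_full_mean_on_homopolymer(self):
        fdef = ft.FeatureDef("x", "aa_composition", "membership", "A")
        assert ft.compute_feature("AAAA", fdef) == 1.0

    def test_scale_sliding_window_max_on_constant_sequence(self):
        from tadscreen.features.encodings import DISORDER_SCALE

        fdef = ft.FeatureDef(
            "x", "disorder", "scale", "disorder", view="window:3", aggregator="max"
        )
        assert ft.compute_feature("EEEEEE", fdef) == pytest.approx(DISORDER_SCALE["E"])

    @settings(max_examples=60, deadline=None)
    @given(PEPTIDES)
    def test_aggregators_match_direct_formulas(self, peptide):
        """Each aggregator over the full view equals its direct recomputation."""
        from tadscreen.features.encodings import DISORDER_SCALE

        values = [DISORDER_SCALE[aa] for aa in peptide]
        for agg, expected in [
            ("sum", sum(values)),
            ("mean", sum(values) / len(values)),
            ("max", max(values)),
        ]:
            fdef = ft.FeatureDef("x", "disorder", "scale", "disorder", aggregator=agg)
            assert ft.compute_feature(peptide, fdef) == pytest.approx(expected)

    def test_nonstandard_residue_rejected(self):
        fdef = ft.FeatureDef("x", "aa_composition", "membership", "A")
        with pytest.raises(InvalidAlphabetError):
            ft.compute_feature("AXA", fdef)

    @settings(max_examples=40, deadline=None)
    @given(PEPTIDES)
    def test_featurize_total_and_deterministic(self, peptide):
        catalog = ft.build_default_catalog()
        row1 = [ft.compute_feature(peptide, d) for d in catalog]
        row2 = [ft.compute_feature(peptide, d) for d in catalog]
        assert row1 == row2
        assert all(np.isfinite(row1))


class TestComposition:
    def test_homopolymer(self):
        comp = ft.aa_composition("AAAA")
        assert comp["A"] == 1.0
        assert sum(v for k, v in comp.items() if k != "A") == 0.0

    def test_order_follows_fixed_alphabet(self):
        assert list(ft.aa_composition("AAAA").keys()) == list(AA_ORDER)

    @settings(max_examples=40, deadline=None)
    @given(PEPTIDES)
    def test_sums_to_one(self, peptide):
        assert sum(ft.aa_composition(peptide).values()) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "peptide,group,value",
        [("DE", "negative", 1.0), ("IVLA", "aliphatic", 1.0),
         ("VD", "hydrophobic", 0.5), ("VD", "negative", 0.5)],
    )
    def test_group_fractions(self, peptide, group, value):
        assert ft.group_composition(peptide)[group] == pytest.approx(value)

    @settings(max_examples=40, deadline=None)
    @given(PEPTIDES)
    def test_group_fractions_bounded(self, peptide):
        comp = ft.group_composition(peptide)
        assert set(comp) == set(AA_GROUPS)
        assert all(0.0 <= v <= 1.0 for v in comp.values())

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            ft.aa_composition("")
        with pytest.raises(ValueError):
            ft.group_composition("")


class TestMinimotif:
    def test_presence_within_gap(self):
        pat = ft.minimotif_pattern("negative", "aromatic", 0, 10)
        assert ft.minimotif_feature("DAF", pat, "presence") == 1

    def test_gap_beyond_limit_no_match(self):
        pat = ft.minimotif_pattern("negative", "aromatic", 0, 10)
        assert ft.minimotif_feature("D" + "A" * 11 + "F", pat, "presence") == 0

    def test_count_on_alternating_sequence(self):
        pat = ft.minimotif_pattern("negative", "aromatic", 0, 10)
        # overlapping-start scan: D at 0 and D at 2 both start a motif
        assert ft.minimotif_feature("DFDF", pat, "count") == 2

    @settings(max_examples=80, deadline=None)
    @given(st.text(alphabet=list("DKFAN"), min_size=1, max_size=12),
           st.sampled_from([("negative", "aromatic", False),
                            ("positive", "negative", False),
                            ("negative", "polar", True),
                            ("aromatic", "nonpolar", True)]),
           st.sampled_from([(0, 2), (3, 6), (7, 10), (0, 10)]))
    def test_count_matches_exhaustive_pair_scan(self, peptide, pair, band):
        g1, g2, symmetric = pair
        lo, hi = band
        pat = ft.minimotif_pattern(g1, g2, lo, hi, symmetric=symmetric)
        got = ft.minimotif_feature(peptide, pat, "count")
        expected = count_minimotif_pairs(
            peptide, MINIMOTIF_GROUPS[g1], MINIMOTIF_GROUPS[g2], lo, hi, symmetric
        )
        assert got == expected
        assert got >= ft.minimotif_feature(peptide, pat, "presence")


class TestNineTAD:
    def test_constructed_match(self):
        # matches pattern 3: acidic start, hydrophobic pair, hydrophobic at 7
        assert ft.nine_aa_tad("DAALLALAA") == 1

    def test_polybasic_no_match(self):
        assert ft.nine_aa_tad("KKKKKKKKK") == 0

    def test_shorter_than_nine_no_match(self):
        assert ft.nine_aa_tad("DALLAL") == 0


class TestScalars:
    def test_hydrophobic_fraction(self):
        assert ft.hydrophobic_fraction("VD") == 0.5

    def test_pi_of_sidechain_free_peptide_is_terminal_midpoint(self):
        # G/A/S... have no titratable side chain: the charge curve zeroes at
        # the midpoint of the terminal pKa values (closed form)
        expected = (PKA_NTERM + PKA_CTERM) / 2
        for pep in ("GG", "AAAA", "SSSTTT"):
            assert ft.isoelectric_point(pep) == pytest.approx(expected, abs=1e-3)

    def test_pi_charge_ordering(self):
        assert ft.isoelectric_point("DDDDDD") < ft.isoelectric_point("KKKKKK")

    @settings(max_examples=40, deadline=None)
    @given(PEPTIDES)
    def test_pi_bisection_converges_to_zero_charge(self, peptide):
        pi = ft.isoelectric_point(peptide)
        assert abs(ft.net_charge(peptide, pi)) < 1e-4

    def test_scalar_block_keys_and_ranges(self):
        props = ft.scalar_properties("MDDFWEE")
        assert props["length"] == 7.0
        assert props["molecular_weight"] > 900
        assert 0.0 <= props["disorder"] <= 1.0
        assert 0.0 <= props["helicity"] <= 1.0

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            ft.scalar_properties("")


class TestEnrichment:
    def test_identical_sets_give_zero_enrichment(self):
        peps = ["DDWF", "KKRA", "MEDF"]
        enr = ft.aa_enrichment(peps, peps)
        assert all(v == pytest.approx(0.0) for v in enr.values())

    def test_toy_counts_match_hand_computation(self):
        enr = ft.aa_enrichment(["DD"], ["KK"])
        # func: D=2.5/12, others 0.5/12; nonfunc: K=2.5/12
        assert enr["D"] == pytest.approx(np.log2(2.5 / 0.5))
        assert enr["K"] == pytest.approx(np.log2(0.5 / 2.5))
        assert enr["A"] == pytest.approx(0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ft.aa_enrichment([], ["KK"])

    def test_acidic_aromatic_up_basic_down_on_planted_labels(self, small_library):
        func = [m.peptide for m in small_library if m.true_class == "functional"]
        nonfunc = [m.peptide for m in small_library
                   if m.true_class == "nonfunctional" and m.peptide]
        enr = ft.aa_enrichment(func, nonfunc)
        assert all(enr[aa] > 0 for aa in "DE")
        assert all(enr[aa] < 0 for aa in "KRH")


class TestMotifEnrichment:
    def test_printed_count_arithmetic(self):
        # motif-vs-label odds ratio on the published 2x2 counts
        assert ft.motif_enrichment(219, 520, 13384, 50001) == pytest.approx(
            1.573, abs=1e-3
        )

    def test_equal_odds(self):
        assert ft.motif_enrichment(10, 20, 30, 60) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ft.motif_enrichment(10, 0, 30, 60)


class TestCompareDistributions:
    def test_identical_samples_symmetric_u(self):
        res = ft.compare_distributions([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["U"] == pytest.approx(8.0)  # n1*n2/2
        assert res["median_difference"] == 0.0

    def test_small_sample_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = list(rng.normal(size=5))
            b = list(rng.normal(size=4))
            res = ft.compare_distributions(a, b)
            assert res["p_value"] == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-9)

    def test_median_difference_sign_matches_shift(self):
        res = ft.compare_distributions([5, 6, 7], [1, 2, 3])
        assert res["median_difference"] > 0
        res = ft.compare_distributions([1, 2, 3], [5, 6, 7])
        assert res["median_difference"] < 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ft.compare_distributions([], [1.0])


class TestFeaturizer:
    def test_transform_shape_and_names(self):
        fz = ft.PeptideFeaturizer().fit([])
        X = fz.transform(["DDWDEE", "KKKK"])
        assert X.shape == (2, 146)
        assert list(X.columns) == list(fz.get_feature_names_out())

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        fz = ft.PeptideFeaturizer()
        clone(fz)  # must not raise
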