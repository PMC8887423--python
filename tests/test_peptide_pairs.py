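"""Discriminating-pair matching and paralog ratio estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from ribopara.digestion import DigestParams, build_peptide_index
from ribopara.peptide_pairs import (
    PeptidePairMatch,
    estimate_pair_ratio,
    find_discriminating_pairs,
    hamming,
)
from ribopara.quantify import SampleDesign
from ribopara.registry import ParalogGroup, ProteinRecord, Registry
from ribopara.synthetic import make_toy_registry


class TestHamming:
    def test_published_rps19_pair_differs_at_two_positions(self):
        # the classic RpS19b/RpS19a discriminating pair
        assert hamming("DIDQHAVTK", "EIDQHVVTK") == 2

    @pytest.mark.parametrize(
        "a, b, expected",
        [("ACD", "ACD", 0), ("ACD", "ACE", 1), ("AAAA", "TTTT", 4)],
    )
    def test_examples(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            hamming("ACD", "ACDE")


def pair_registry(middle_can="DIDQHAVTK", middle_alt="EIDQHVVTK"):
    can = "ANSVELK" + middle_can + "GWFNTYR"
    alt = "ANSVELK" + middle_alt + "GWFNTYR"
    return Registry(
        [
            ProteinRecord("CAN", "can", can, "SSU", "G", "canonical"),
            ProteinRecord("ALT", "alt", alt, "SSU", "G", "alternative"),
        ],
        [ParalogGroup("G", "CAN", "ALT", can == alt)],
    )


PARAMS0 = DigestParams(max_missed=0)


class TestFindPairs:
    def test_single_substituted_peptide_matched(self):
        reg = pair_registry(middle_alt="DIDQHVVTK")  # one substitution
        (match,) = find_discriminating_pairs(reg, "G", PARAMS0)
        assert match.pep_canonical == "DIDQHAVTK"
        assert match.pep_alternative == "DIDQHVVTK"
        assert match.n_subs == 1
        assert match.sub_positions == (6,)
        assert match.anchored
        assert match.start_canonical == match.start_alternative == 8

    def test_two_substitutions_reported_with_positions(self):
        reg = pair_registry()
        (match,) = find_discriminating_pairs(reg, "G", PARAMS0)
        assert match.n_subs == 2
        assert match.sub_positions == (1, 6)
        assert match.label == "[D]IDQH[A]VTK/[E]IDQH[V]VTK"

    def test_identical_pair_yields_empty(self):
        reg = pair_registry(middle_alt="DIDQHAVTK")
        assert find_discriminating_pairs(reg, "G", PARAMS0) == []

    def test_destroyed_cleavage_site_prevents_match(self):
        # K->Q removes a cut site; the alternative's peptides change length
        can = "AAADDDK" + "CCCEEEK" + "FFFGGGR"
        alt = "AAADDDK" + "CCCEEEQ" + "FFFGGGR"
        reg = Registry(
            [
                ProteinRecord("CAN", "can", can, "SSU", "G", "canonical"),
                ProteinRecord("ALT", "alt", alt, "SSU", "G", "alternative"),
            ],
            [ParalogGroup("G", "CAN", "ALT", False)],
        )
        assert find_discriminating_pairs(reg, "G", PARAMS0) == []

    def test_match_count_monotone_in_max_subs(self):
        reg = make_toy_registry(subs_per_block=2, seed=13)
        counts = [
            len(find_discriminating_pairs(reg, "G1", max_subs=s))
            for s in (1, 2, 3)
        ]
        assert counts == sorted(counts)

    def test_matched_peptides_are_disjointly_unique(self, bundled_registry, bundled_index):
        for gid in ("RpS19", "RpL22"):
            for m in find_discriminating_pairs(
                bundled_registry, gid, index=bundled_index
            ):
                assert bundled_index.parents_of(m.pep_canonical) == frozenset(
                    {bundled_registry.group(gid).canonical}
                )
                assert bundled_index.parents_of(m.pep_alternative) == frozenset(
                    {bundled_registry.group(gid).alternative}
                )

    def test_each_peptide_used_at_most_once(self, bundled_registry, bundled_index):
        matches = find_discriminating_pairs(
            bundled_registry, "RpS5", index=bundled_index
        )
        cans = [m.pep_canonical for m in matches]
        alts = [m.pep_alternative for m in matches]
        assert len(cans) == len(set(cans))
        assert len(alts) == len(set(alts))

    def test_bad_bounds_rejected(self):
        reg = pair_registry()
        with pytest.raises(ValueError):
            find_discriminating_pairs(reg, "G", min_subs=0)
        with pytest.raises(ValueError):
            find_discriminating_pairs(reg, "G", min_subs=2, max_subs=1)


DESIGN = SampleDesign(
    pd.DataFrame(
        [
            ("TMT1", "c01", "testis", "m80S", "rep1", False),
            ("TMT1", "c02", "ovary", "m80S", "rep1", False),
        ],
        columns=SampleDesign.COLUMNS,
    )
)


def match(pep_can, pep_alt, anchored=True):
    return PeptidePairMatch(
        group_id="G",
        pep_canonical=pep_can,
        pep_alternative=pep_alt,
        n_subs=hamming(pep_can, pep_alt),
        sub_positions=tuple(
            i + 1 for i, (x, y) in enumerate(zip(pep_can, pep_alt)) if x != y
        ),
        anchored=anchored,
        start_canonical=1,
        start_alternative=1,
    )


def psms(rows):
    return pd.DataFrame(
        [
            {
                "peptide": pep,
                "proteins": (prot,),
                "charge": charge,
                "run": "TMT1",
                "qvalue": 0.01,
                "sn_c01": sn_testis,
                "sn_c02": sn_ovary,
            }
            for pep, prot, charge, sn_testis, sn_ovary in rows
        ]
    )


class TestEstimate:
    def test_equal_signal_gives_zero(self):
        est = estimate_pair_ratio(
            [match("DIDQHAVTK", "EIDQHVVTK")],
            psms([("DIDQHAVTK", "CAN", 2, 4.0, 1.0), ("EIDQHVVTK", "ALT", 2, 4.0, 9.0)]),
            DESIGN,
            "testis",
        )
        assert est.log2_diff == 0.0
        assert est.n_pairs_used == 1

    def test_fourfold_alternative_gives_two(self):
        est = estimate_pair_ratio(
            [match("DIDQHAVTK", "EIDQHVVTK")],
            psms([("DIDQHAVTK", "CAN", 2, 2.0, 1.0), ("EIDQHVVTK", "ALT", 2, 8.0, 1.0)]),
            DESIGN,
            "testis",
        )
        assert est.log2_diff == 2.0

    def test_sums_across_psms_of_same_peptide(self):
        est = estimate_pair_ratio(
            [match("DIDQHAVTK", "EIDQHVVTK")],
            psms(
                [
                    ("DIDQHAVTK", "CAN", 2, 2.0, 1.0),
                    ("DIDQHAVTK", "CAN", 3, 2.0, 1.0),
                    ("EIDQHVVTK", "ALT", 2, 16.0, 1.0),
                ]
            ),
            DESIGN,
            "testis",
        )
        assert est.log2_diff == 2.0

    def test_median_over_pairs(self):
        table = psms(
            [
                ("ADIDQHAVTK", "CAN", 2, 1.0, 1.0), ("AEIDQHVVTK", "ALT", 2, 2.0, 1.0),
                ("CDIDQHAVTK", "CAN", 2, 1.0, 1.0), ("CEIDQHVVTK", "ALT", 2, 1.0, 1.0),
                ("DDIDQHAVTK", "CAN", 2, 1.0, 1.0), ("DEIDQHVVTK", "ALT", 2, 32.0, 1.0),
            ]
        )
        matches = [
            match("ADIDQHAVTK", "AEIDQHVVTK"),
            match("CDIDQHAVTK", "CEIDQHVVTK"),
            match("DDIDQHAVTK", "DEIDQHVVTK"),
        ]
        est = estimate_pair_ratio(matches, table, DESIGN, "testis")
        assert sorted(est.per_pair.values()) == [0.0, 1.0, 5.0]
        assert est.log2_diff == 1.0

    def test_zero_sided_pairs_skipped_and_counted(self):
        table = psms(
            [
                ("ADIDQHAVTK", "CAN", 2, 1.0, 1.0), ("AEIDQHVVTK", "ALT", 2, 4.0, 1.0),
                ("CDIDQHAVTK", "CAN", 2, 0.0, 1.0), ("CEIDQHVVTK", "ALT", 2, 1.0, 1.0),
            ]
        )
        matches = [
            match("ADIDQHAVTK", "AEIDQHVVTK"),
            match("CDIDQHAVTK", "CEIDQHVVTK"),
        ]
        est = estimate_pair_ratio(matches, table, DESIGN, "testis")
        assert est.n_pairs_used == 1
        assert est.n_pairs_skipped == 1
        assert est.log2_diff == 2.0

    def test_no_usable_pairs_yields_undefined_estimate(self):
        est = estimate_pair_ratio(
            [match("DIDQHAVTK", "EIDQHVVTK")],
            psms([("DIDQHAVTK", "CAN", 2, 1.0, 1.0)]),
            DESIGN,
            "testis",
        )
        assert est.log2_diff is None
        assert est.n_pairs_used == 0

    def test_unanchored_pairs_excluded_by_default(self):
        table = psms(
            [("DIDQHAVTK", "CAN", 2, 1.0, 1.0), ("EIDQHVVTK", "ALT", 2, 4.0, 1.0)]
        )
        m = match("DIDQHAVTK", "EIDQHVVTK", anchored=False)
        assert estimate_pair_ratio([m], table, DESIGN, "testis").log2_diff is None
        est = estimate_pair_ratio([m], table, DESIGN, "testis", anchored_only=False)
        assert est.log2_diff == 2.0

    def test_charge_overlap_filter(self):
        table = psms(
            [("DIDQHAVTK", "CAN", 2, 1.0, 1.0), ("EIDQHVVTK", "ALT", 3, 4.0, 1.0)]
        )
        m = match("DIDQHAVTK", "EIDQHVVTK")
        est = estimate_pair_ratio(
            [m], table, DESIGN, "testis", require_charge_overlap=True
        )
        assert est.log2_diff is None

    def test_mean_method_divides_by_psm_count(self):
        table = psms(
            [
                ("DIDQHAVTK", "CAN", 2, 2.0, 1.0),
                ("DIDQHAVTK", "CAN", 2, 2.0, 1.0),
                ("EIDQHVVTK", "ALT", 2, 4.0, 1.0),
            ]
        )
        m = match("DIDQHAVTK", "EIDQHVVTK")
        assert estimate_pair_ratio([m], table, DESIGN, "testis").log2_diff == 0.0
        est = estimate_pair_ratio([m], table, DESIGN, "testis", method="mean")
        assert est.log2_diff == 1.0

    def test_label_swap_negates_estimates(self):
        table = psms(
            [("DIDQHAVTK", "CAN", 2, 2.0, 1.0), ("EIDQHVVTK", "ALT", 2, 8.0, 1.0)]
        )
        fwd = estimate_pair_ratio(
            [match("DIDQHAVTK", "EIDQHVVTK")], table, DESIGN, "testis"
        )
        rev = estimate_pair_ratio(
            [match("EIDQHVVTK", "DIDQHAVTK")], table, DESIGN, "testis"
        )
        assert fwd.log2_diff == -rev.log2_diff

    def test_tissue_selection_uses_design(self):
        table = psms(
            [("DIDQHAVTK", "CAN", 2, 2.0, 1.0), ("EIDQHVVTK", "ALT", 2, 8.0, 4.0)]
        )
        m = match("DIDQHAVTK", "EIDQHVVTK")
        assert estimate_pair_ratio([m], table, DESIGN, "testis").log2_diff == 2.0
        assert estimate_pair_ratio([m], table, DESIGN, "ovary").log2_diff == 2.0
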