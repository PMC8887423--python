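"""PSM filtering, abundance aggregation, normalization, scaling, Z-scores."""

import io

import numpy as np
import pandas as pd
import pytest

from ribopara.digestion import DigestParams, build_peptide_index
from ribopara.quantify import (
    AbundanceMatrix,
    SampleDesign,
    aggregate,
    filter_psms,
    normalize_total,
    read_psm_table,
    row_zscores,
    scale,
    write_psm_table,
)
from ribopara.registry import ParalogGroup, ProteinRecord, Registry

REGISTRY = Registry(
    [
        ProteinRecord("CAN", "can", "ANSVELK" + "DIDQHAVTK" + "GWFNTYR", "SSU", "G", "canonical"),
        ProteinRecord("ALT", "alt", "ANSVELK" + "EIDQHVVTK" + "GWFNTYR", "SSU", "G", "alternative"),
    ],
    [ParalogGroup("G", "CAN", "ALT", False)],
)


def psm_frame(rows):
    """rows: (peptide, proteins, run, qvalue, sn dict)"""
    channels = sorted({ch for *_, sn in rows for ch in sn})
    data = []
    for pep, prots, run, q, sn in rows:
        data.append(
            {
                "peptide": pep,
                "proteins": tuple(prots),
                "charge": 2,
                "run": run,
                "qvalue": q,
                **{f"sn_{c}": sn.get(c, np.nan) for c in channels},
            }
        )
    return pd.DataFrame(data)


def design(rows):
    return SampleDesign(pd.DataFrame(rows, columns=SampleDesign.COLUMNS))


TWO_CHANNEL = design(
    [
        ("TMT1", "c01", "testis", "m80S", "rep1", False),
        ("TMT1", "c02", "ovary", "m80S", "rep1", False),
    ]
)


class TestFilter:
    def test_qvalue_boundary_inclusive(self):
        psms = psm_frame(
            [
                ("DIDQHAVTK", ["CAN"], "TMT1", 0.05, {"c01": 1.0}),
                ("DIDQHAVTK", ["CAN"], "TMT1", 0.06, {"c01": 1.0}),
                ("DIDQHAVTK", ["CAN"], "TMT1", np.nan, {"c01": 1.0}),
            ]
        )
        out = filter_psms(psms, max_qvalue=0.05)
        # 0.05 retained (inclusive 5% FDR), 0.06 removed, missing q retained
        assert len(out) == 2
        assert 0.06 not in set(out["qvalue"].dropna())

    def test_unique_filter_drops_shared_peptides(self):
        index = build_peptide_index(REGISTRY, DigestParams(max_missed=0))
        psms = psm_frame(
            [
                ("DIDQHAVTK", ["CAN"], "TMT1", 0.01, {"c01": 1.0}),
                ("ANSVELK", ["CAN", "ALT"], "TMT1", 0.01, {"c01": 1.0}),
            ]
        )
        out = filter_psms(psms, require_unique=True, index=index)
        assert list(out["peptide"]) == ["DIDQHAVTK"]

    def test_unique_filter_requires_index(self):
        with pytest.raises(ValueError, match="peptide index"):
            filter_psms(psm_frame([("A", ["CAN"], "TMT1", 0.01, {"c01": 1})]),
                        require_unique=True)


class TestAggregate:
    def test_sums_sn_per_protein_channel(self):
        psms = psm_frame(
            [
                ("DIDQHAVTK", ["CAN"], "TMT1", 0.01, {"c01": 10.0, "c02": 1.0}),
                ("GWFNTYR", ["CAN"], "TMT1", 0.01, {"c01": 5.0, "c02": 2.0}),
            ]
        )
        m = aggregate(psms, REGISTRY, TWO_CHANNEL)
        assert m.stage == "raw"
        assert m.values.at["CAN", ("TMT1", "c01")] == 15.0
        assert m.values.at["CAN", ("TMT1", "c02")] == 3.0

    def test_missing_reporter_contributes_nothing(self):
        psms = psm_frame(
            [
                ("DIDQHAVTK", ["CAN"], "TMT1", 0.01, {"c01": 10.0}),
                ("GWFNTYR", ["CAN"], "TMT1", 0.01, {"c01": 5.0, "c02": 2.0}),
            ]
        )
        m = aggregate(psms, REGISTRY, TWO_CHANNEL)
        assert m.values.at["CAN", ("TMT1", "c01")] == 15.0
        assert m.values.at["CAN", ("TMT1", "c02")] == 2.0

    def test_undetected_protein_absent_not_zero(self):
        psms = psm_frame([("DIDQHAVTK", ["CAN"], "TMT1", 0.01, {"c01": 1.0})])
        m = aggregate(psms, REGISTRY, TWO_CHANNEL)
        assert "ALT" not in m.values.index
        # channel with no reporter at all is a missing cell, not zero
        assert np.isnan(m.values.at["CAN", ("TMT1", "c02")])

    def test_unknown_accession_raises_with_offenders(self):
        psms = psm_frame([("DIDQHAVTK", ["NOPE"], "TMT1", 0.01, {"c01": 1.0})])
        with pytest.raises(ValueError, match="NOPE"):
            aggregate(psms, REGISTRY, TWO_CHANNEL)

    def test_aggregation_additive_under_table_split(self):
        rng = np.random.default_rng(42)
        rows = [
            (
                "DIDQHAVTK" if i % 2 else "GWFNTYR",
                ["CAN"],
                "TMT1",
                0.01,
                {"c01": float(rng.uniform(1, 10)), "c02": float(rng.uniform(1, 10))},
            )
            for i in range(20)
        ]
        psms = psm_frame(rows)
        whole = aggregate(psms, REGISTRY, TWO_CHANNEL).values
        part = (
            aggregate(psms.iloc[:7], REGISTRY, TWO_CHANNEL)
            .values.add(aggregate(psms.iloc[7:], REGISTRY, TWO_CHANNEL).values, fill_value=0)
        )
        pd.testing.assert_frame_equal(whole, part)


class TestNormalize:
    def matrix(self, data, design_obj=TWO_CHANNEL):
        cols = pd.MultiIndex.from_tuples(design_obj.columns(), names=["run", "channel"])
        values = pd.DataFrame(data, columns=cols, dtype=float)
        return AbundanceMatrix(values=values, stage="raw", design=design_obj)

    def test_mean_total_target(self):
        m = normalize_total(self.matrix([[100.0, 200.0]]))
        assert m.stage == "normalized"
        assert list(m.values.iloc[0]) == [150.0, 150.0]

    def test_equal_totals_unchanged(self):
        m = self.matrix([[3.0, 3.0], [7.0, 7.0]])
        out = normalize_total(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_totals_equal_and_ratios_preserved(self):
        rng = np.random.default_rng(0)
        m = self.matrix(rng.uniform(1, 100, size=(30, 2)))
        out = normalize_total(m)
        totals = out.values.sum(axis=0)
        assert np.allclose(totals, totals.mean(), rtol=1e-9)
        for col in m.values.columns:
            ratio_before = m.values[col] / m.values[col].sum()
            ratio_after = out.values[col] / out.values[col].sum()
            assert np.allclose(ratio_before, ratio_after, rtol=1e-12)

    def test_zero_total_column_rejected(self):
        with pytest.raises(ValueError, match="non-positive total"):
            normalize_total(self.matrix([[1.0, 0.0]]))

    def test_stage_transitions_enforced(self):
        m = normalize_total(self.matrix([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="requires stage"):
            normalize_total(m)


class TestScale:
    DESIGN = design(
        [
            ("TMT1", "c01", "testis", "m80S", "rep1", False),
            ("TMT1", "c02", "ovary", "m80S", "rep1", False),
            ("TMT1", "c03", "pool", "m80S", "rep1", True),
        ]
    )

    def matrix(self, data):
        cols = pd.MultiIndex.from_tuples(self.DESIGN.columns(), names=["run", "channel"])
        return AbundanceMatrix(
            values=pd.DataFrame(data, columns=cols, dtype=float),
            stage="normalized",
            design=self.DESIGN,
        )

    def test_pooled_reference(self):
        out = scale(self.matrix([[8.0, 2.0, 4.0]]), "pooled")
        assert out.stage == "scaled"
        assert list(out.values.iloc[0]) == [2.0, 0.5, 1.0]

    def test_pooled_channel_maps_to_one(self):
        out = scale(self.matrix([[8.0, 2.0, 4.0], [3.0, 9.0, 6.0]]), "pooled")
        assert list(out.values[("TMT1", "c03")]) == [1.0, 1.0]

    def test_replicate_mean_reference(self):
        out = scale(self.matrix([[2.0, 4.0, 100.0]]), "replicate_mean")
        np.testing.assert_allclose(
            out.values.iloc[0, :2].to_numpy(), [2 / 3, 4 / 3]
        )

    def test_all_equal_gives_ones(self):
        out = scale(self.matrix([[5.0, 5.0, 5.0]]), "pooled")
        assert list(out.values.iloc[0]) == [1.0, 1.0, 1.0]

    def test_missing_reference_gives_missing_cells(self):
        out = scale(self.matrix([[8.0, 2.0, np.nan]]), "pooled")
        assert out.values.iloc[0].isna().all()

    def test_pooled_mode_requires_pooled_channel(self):
        m = self.matrix([[8.0, 2.0, 4.0]])
        m.design = TWO_CHANNEL
        m.values = m.values[[("TMT1", "c01"), ("TMT1", "c02")]]
        with pytest.raises(ValueError, match="no pooled channel"):
            scale(m, "pooled", TWO_CHANNEL)


class TestZScores:
    def matrix(self, data, stage="normalized"):
        d = design(
            [
                ("TMT1", "c01", "a", "m80S", "rep1", False),
                ("TMT1", "c02", "b", "m80S", "rep1", False),
                ("TMT1", "c03", "c", "m80S", "rep1", False),
            ]
        )
        cols = pd.MultiIndex.from_tuples(d.columns(), names=["run", "channel"])
        return AbundanceMatrix(
            values=pd.DataFrame(data, columns=cols, dtype=float), stage=stage, design=d
        )

    def test_simple_row(self):
        out = row_zscores(self.matrix([[1.0, 2.0, 3.0]]))
        assert out.stage == "zscore"
        assert list(out.values.iloc[0]) == [-1.0, 0.0, 1.0]

    def test_constant_row_maps_to_zero(self):
        out = row_zscores(self.matrix([[5.0, 5.0, 5.0]]))
        assert list(out.values.iloc[0]) == [0.0, 0.0, 0.0]

    def test_rows_standardised(self):
        rng = np.random.default_rng(1)
        out = row_zscores(self.matrix(rng.uniform(1, 9, size=(10, 3))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_short_rows_dropped(self):
        out = row_zscores(self.matrix([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]]))
        assert len(out.values) == 1


def test_psm_table_round_trip(tmp_path):
    psms = psm_frame(
        [
            ("DIDQHAVTK", ["CAN"], "TMT1", 0.01, {"c01": 10.0, "c02": 1.0}),
            ("ANSVELK", ["CAN", "ALT"], "TMT1", np.nan, {"c01": 5.0}),
        ]
    )
    path = tmp_path / "psms.tsv"
    write_psm_table(psms, path)
    back = read_psm_table(path)
    assert list(back["proteins"]) == [("CAN",), ("CAN", "ALT")]
    assert np.isnan(back.loc[1, "sn_c02"])
    pd.testing.assert_frame_equal(back[psms.columns], psms)


def test_matrix_file_round_trip(tmp_path):
    cols = pd.MultiIndex.from_tuples(TWO_CHANNEL.columns(), names=["run", "channel"])
    m = AbundanceMatrix(
        values=pd.DataFrame([[1.5, np.nan]], index=["CAN"], columns=cols),
        stage="normalized",
        design=TWO_CHANNEL,
    )
    path = tmp_path / "matrix.tsv"
    m.write(path)
    back = AbundanceMatrix.read(path, TWO_CHANNEL)
    assert back.stage == "normalized"
    pd.testing.assert_frame_equal(back.values, m.values, check_names=False)
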