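"""Satellite-account construction: concordances, records, weighting."""

import numpy as np
import pytest

import basinfoot as bf
from basinfoot.satellite import build_concordances
from conftest import table_from_A


def make_weights(table, co2=None, area=None, hii=None):
    return bf.WeightData(
        gross_output=table.X,
        co2=np.ones(table.n) if co2 is None else np.asarray(co2, float),
        area=area or {},
        hii=hii or {b: 1.0 for b in table.basins},
    )


@pytest.fixture(scope="module")
def toy_table():
    """2 basins x 2 sectors, mild trade, all outputs positive."""
    A = np.array(
        [
            [0.2, 0.1, 0.05, 0.0],
            [0.0, 0.2, 0.0, 0.05],
            [0.05, 0.0, 0.2, 0.1],
            [0.0, 0.05, 0.0, 0.2],
        ]
    )
    Y = np.array(
        [[8.0, 2.0, 1.0], [6.0, 1.0, 1.0], [2.0, 9.0, 1.0], [1.0, 7.0, 1.0]]
    )
    return table_from_A(A, Y, m=2, c=2)


class TestExpandConcordance:
    def test_block_placement(self):
        basins, sectors = ("B01", "B02"), ("S01", "S02")
        B1 = np.array([[1.0, 0.0]])
        row = bf.expand_concordance(B1, "B02", basins, sectors)
        np.testing.assert_array_equal(row, [[0.0, 0.0, 1.0, 0.0]])

    def test_all_zero_input_stays_zero(self):
        out = bf.expand_concordance(np.zeros((3, 2)), "B01", ("B01",), ("S01", "S02"))
        assert out.shape == (3, 2) and not out.any()

    def test_multi_basin_shapes_and_block_structure(self):
        # 4 threat causes x 15 basin-sectors (3 basins x 5 sectors)
        basins = ("B01", "B02", "B03")
        sectors = tuple(f"S{i:02d}" for i in range(1, 6))
        B1 = np.zeros((4, 5))
        B1[0, 0] = B1[1, 2] = B1[2, 4] = B1[3, 1] = 1.0
        for b, basin in enumerate(basins):
            Bc = bf.expand_concordance(B1, basin, basins, sectors)
            assert Bc.shape == (4, 15)
            np.testing.assert_array_equal(Bc[:, b * 5:(b + 1) * 5], B1)
            outside = np.delete(Bc, np.s_[b * 5:(b + 1) * 5], axis=1)
            assert not outside.any()

    def test_unknown_basin_raises(self):
        with pytest.raises(KeyError):
            bf.expand_concordance(np.ones((1, 2)), "nope", ("B01",), ("S01", "S02"))


class TestNormalizeConcordance:
    def test_output_weighted_rows(self):
        factors = [bf.ThreatFactor("F1")]
        Bc = np.array([[1.0, 1.0, 0.0]])
        w = bf.WeightData(gross_output=[100.0, 300.0, 50.0], co2=np.ones(3),
                          area={}, hii={})
        np.testing.assert_allclose(
            bf.normalize_concordance(Bc, w, factors), [[0.25, 0.75, 0.0]]
        )

    def test_climate_rows_use_co2(self):
        factors = [bf.ThreatFactor("F1", is_climate_change=True)]
        Bc = np.array([[1.0, 1.0, 1.0]])
        w = bf.WeightData(gross_output=[1.0, 1.0, 1.0], co2=[10.0, 30.0, 60.0],
                          area={}, hii={})
        np.testing.assert_allclose(
            bf.normalize_concordance(Bc, w, factors), [[0.1, 0.3, 0.6]]
        )

    def test_zero_weight_row_becomes_all_zero(self):
        factors = [bf.ThreatFactor("F1")]
        Bc = np.array([[0.0, 1.0]])
        w = bf.WeightData(gross_output=[5.0, 0.0], co2=np.ones(2), area={}, hii={})
        assert not bf.normalize_concordance(Bc, w, factors).any()

    def test_negative_weights_rejected(self):
        with pytest.raises(bf.SatelliteError):
            bf.WeightData(gross_output=[-1.0], co2=[1.0], area={}, hii={})


class TestRecordMapping:
    def test_mapped_rows_are_stochastic(self, toy_table):
        factors = [bf.ThreatFactor("F1"), bf.ThreatFactor("F2")]
        B1 = np.array([[1.0, 1.0], [0.0, 0.0]])  # F2 maps to nothing
        weights = make_weights(toy_table)
        conc = build_concordances(B1, factors, weights,
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet(
            (("sp1", "B01", "F1"), ("sp1", "B01", "F2"), ("sp2", "B02", "F1"))
        )
        C = bf.map_records(records, conc)
        np.testing.assert_allclose(C.sum(axis=1), [1.0, 0.0, 1.0], atol=1e-12)
        # each record row lives in its own basin's block
        assert not C[0, 2:].any() and not C[2, :2].any()

    def test_unknown_factor_raises(self, toy_table):
        conc = build_concordances(np.ones((1, 2)), [bf.ThreatFactor("F1")],
                                  make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        with pytest.raises(bf.SatelliteError, match="unknown factor"):
            bf.map_records(bf.ThreatRecordSet((("sp1", "B01", "F9"),)), conc)

    def test_duplicate_records_rejected(self):
        with pytest.raises(bf.SatelliteError, match="duplicate"):
            bf.ThreatRecordSet((("sp1", "B01", "F1"), ("sp1", "B01", "F1")))


class TestAggregation:
    def test_rowsums_count_mapped_causes_and_mass_is_conserved(self, toy_table):
        factors = [bf.ThreatFactor(f"F{i}") for i in range(1, 4)]
        B1 = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        conc = build_concordances(B1, factors, make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet(
            (("sp1", "B01", "F1"), ("sp1", "B01", "F2"), ("sp1", "B01", "F3"),
             ("sp1", "B02", "F1"), ("sp2", "B02", "F2"))
        )
        C = bf.map_records(records, conc)
        C_ag, pairs = bf.aggregate_records(C, records)
        assert pairs == (("sp1", "B01"), ("sp1", "B02"), ("sp2", "B02"))
        np.testing.assert_allclose(C_ag.sum(axis=1), [3.0, 1.0, 1.0], atol=1e-10)
        assert C_ag.sum() == pytest.approx(C.sum(), abs=1e-12)

    def test_distinct_pairs_leave_matrix_unchanged(self, toy_table):
        factors = [bf.ThreatFactor("F1")]
        conc = build_concordances(np.array([[1.0, 1.0]]), factors,
                                  make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet((("sp1", "B01", "F1"), ("sp2", "B02", "F1")))
        C = bf.map_records(records, conc)
        C_ag, _ = bf.aggregate_records(C, records)
        np.testing.assert_array_equal(C_ag, C)


class TestWeighting:
    def test_single_pair_species_sums_to_one(self, toy_table):
        factors = [bf.ThreatFactor("F1")]
        conc = build_concordances(np.array([[1.0, 0.0]]), factors,
                                  make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet((("sp1", "B01", "F1"),))
        C = bf.map_records(records, conc)
        C_ag, pairs = bf.aggregate_records(C, records)
        weights = make_weights(toy_table, area={("sp1", "B01"): 3.0},
                               hii={"B01": 2.0, "B02": 1.0})
        R, lost = bf.weight_and_normalize(C_ag, pairs, records, weights)
        assert R.sum() == pytest.approx(1.0, abs=1e-12) and not lost

    def test_basin_weights_proportional_to_area_times_hii(self, toy_table):
        factors = [bf.ThreatFactor("F1")]
        conc = build_concordances(np.array([[1.0, 0.0]]), factors,
                                  make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet(
            (("sp1", "B01", "F1"), ("sp1", "B02", "F1"))
        )
        C = bf.map_records(records, conc)
        C_ag, pairs = bf.aggregate_records(C, records)
        weights = make_weights(
            toy_table,
            area={("sp1", "B01"): 1.0, ("sp1", "B02"): 3.0},
            hii={"B01": 2.0, "B02": 2.0},
        )
        R, _ = bf.weight_and_normalize(C_ag, pairs, records, weights)
        np.testing.assert_allclose(R.sum(axis=1), [0.25, 0.75], atol=1e-12)

    def test_uniform_weights_match_equal_weight_oracle(self, study_system):
        """With uniform areas/HII the account reduces to plain equal weighting."""
        table, _, records, factors, B1, _ = study_system
        uniform = bf.WeightData(
            gross_output=table.X, co2=np.ones(table.n),
            area={p: 1.0 for p in records.pairs},
            hii={b: 1.0 for b in table.basins},
        )
        conc = build_concordances(B1, factors, uniform, table.basins, table.sectors)
        C = bf.map_records(records, conc)
        C_ag, pairs = bf.aggregate_records(C, records)
        R, _ = bf.weight_and_normalize(C_ag, pairs, records, uniform)
        R_ag, species = bf.aggregate_species(R, pairs)

        # oracle: loop over records, each species splits 1 equally over its
        # basins and each basin share equally over that pair's causes
        fidx = {f.id: i for i, f in enumerate(factors)}
        n_basins = {}
        n_causes = {}
        for s, b, _ in records.records:
            n_causes[(s, b)] = n_causes.get((s, b), 0) + 1
        for s, b in {(s, b) for s, b, _ in records.records}:
            n_basins[s] = n_basins.get(s, 0) + 1
        expected = {s: np.zeros(table.n) for s in dict.fromkeys(r[0] for r in records.records)}
        for s, b, k in records.records:
            row = conc.Nc[b][fidx[k]]
            expected[s] += row / (n_basins[s] * n_causes[(s, b)])
        for i, s in enumerate(species):
            np.testing.assert_allclose(R_ag[i], expected[s], atol=1e-10)

    def test_unattributable_causes_renormalize_or_drop(self, toy_table):
        factors = [bf.ThreatFactor("F1"), bf.ThreatFactor("F2")]
        B1 = np.array([[1.0, 0.0], [0.0, 0.0]])  # F2 unmappable
        conc = build_concordances(B1, factors, make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet(
            (("sp1", "B01", "F1"), ("sp1", "B01", "F2"))
        )
        C = bf.map_records(records, conc)
        C_ag, pairs = bf.aggregate_records(C, records)
        weights = make_weights(toy_table, area={("sp1", "B01"): 1.0})
        R_renorm, lost = bf.weight_and_normalize(C_ag, pairs, records, weights)
        assert R_renorm.sum() == pytest.approx(1.0, abs=1e-12)
        R_drop, lost_d = bf.weight_and_normalize(
            C_ag, pairs, records, weights, unattributable="drop"
        )
        assert R_drop.sum() == pytest.approx(0.5, abs=1e-12)
        assert lost_d["sp1"] == pytest.approx(0.5, abs=1e-12)

    def test_zero_total_weight_species_raises(self, toy_table):
        factors = [bf.ThreatFactor("F1")]
        conc = build_concordances(np.array([[1.0, 0.0]]), factors,
                                  make_weights(toy_table),
                                  toy_table.basins, toy_table.sectors)
        records = bf.ThreatRecordSet((("sp1", "B01", "F1"),))
        C = bf.map_records(records, conc)
        C_ag, pairs = bf.aggregate_records(C, records)
        weights = make_weights(toy_table, area={("sp1", "B01"): 0.0})
        with pytest.raises(bf.SatelliteError, match="sp1"):
            bf.weight_and_normalize(C_ag, pairs, records, weights)


class TestSpeciesAggregation:
    def test_every_species_row_sums_to_one(self, account):
        np.testing.assert_allclose(
            account.R_ag.sum(axis=1), np.ones(len(account.species)), atol=1e-10
        )

    def test_total_mass_equals_species_count(self, account):
        assert account.R.sum() == pytest.approx(len(account.species), abs=1e-8)
        assert account.R_ag.sum() == pytest.approx(len(account.species), abs=1e-8)

    def test_record_order_invariance(self, study_system):
        table, _, records, factors, B1, weights = study_system
        rng = np.random.default_rng(5)
        perm = tuple(records.records[i]
                     for i in rng.permutation(len(records.records)))
        acc1, _ = bf.build_satellite_account(records, factors, B1, weights, table)
        acc2, _ = bf.build_satellite_account(
            bf.ThreatRecordSet(perm), factors, B1, weights, table
        )
        by_species_1 = dict(zip(acc1.species, acc1.R_ag))
        by_species_2 = dict(zip(acc2.species, acc2.R_ag))
        assert set(by_species_1) == set(by_species_2)
        for s in by_species_1:
            np.testing.assert_allclose(by_species_1[s], by_species_2[s], atol=1e-12)


class TestIntensities:
    def test_division_by_output(self, toy_table):
        R_ag = np.zeros((1, toy_table.n))
        R_ag[0, 2] = 0.5
        intens = bf.intensities(R_ag, ("sp1",), toy_table)
        assert intens.Phi[0, 2] == pytest.approx(0.5 / toy_table.X[2])

    def test_conservation_identity(self, table, account, intensity):
        assert float((intensity.Phi * table.X).sum()) == pytest.approx(
            len(account.species), rel=1e-10
        )

    def test_homogeneity_in_output(self, table, intensity):
        doubled = bf.MRIOTable(table.basins, table.sectors, 2 * table.Z,
                               2 * table.Y, 2 * table.V, 2 * table.X,
                               table.primary_inputs)
        intens2 = bf.intensities(intensity.Phi * table.X[np.newaxis, :],
                                 intensity.species, doubled)
        np.testing.assert_allclose(intens2.Phi, intensity.Phi / 2, rtol=1e-12)

    def test_mass_on_zero_output_sector_raises(self):
        Z = np.array([[2.0, 0.0], [0.0, 0.0]])
        from conftest import table_from_ZX
        dead = table_from_ZX(Z, [10.0, 0.0], 1, 2)
        R_ag = np.array([[0.0, 1.0]])
        with pytest.raises(bf.SatelliteError, match="zero-output"):
            bf.intensities(R_ag, ("sp1",), dead)


class TestAccountIO:
    def test_inputs_round_trip(self, study_system, tmp_path):
        from basinfoot.satellite import load_account_inputs, save_account_inputs
        table, _, records, factors, B1, weights = study_system
        bf.save_table(table, tmp_path)
        save_account_inputs(tmp_path, records, factors, B1, weights,
                            table.basins, table.sectors)
        loaded = load_account_inputs(tmp_path, bf.load_table(tmp_path))
        records2, factors2, B1_2, weights2 = loaded
        assert records2.records == records.records
        assert [f.id for f in factors2] == [f.id for f in factors]
        assert [f.is_climate_change for f in factors2] == [
            f.is_climate_change for f in factors
        ]
        np.testing.assert_array_equal(B1_2, B1)
        np.testing.assert_allclose(weights2.co2, weights.co2, rtol=1e-12)
        assert weights2.area.keys() == weights.area.keys()
        assert weights2.hii == pytest.approx(weights.hii)
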