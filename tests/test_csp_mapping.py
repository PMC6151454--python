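"""Normalized chemical-shift perturbation and region calling."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cambind.csp_mapping import (
    CSPRecord,
    ShiftTable,
    compute_csp,
    perturbed_regions,
    read_shift_table,
    write_shift_table,
)
from cambind.errors import FormatError
from cambind.synthetic_data import simulate_shift_tables


def _table(rows, label="free"):
    return ShiftTable(
        data=pd.DataFrame(rows, columns=["residue", "res_name", "delta_HN", "delta_N"]),
        label=label,
    )


class TestReadShiftTable:
    def test_simple_csv(self):
        text = "residue,res_name,HN,N\n2,ALA,8.1,120.5\n3,GLY,7.9,108.2\n4,LEU,8.4,122.0\n"
        table = read_shift_table(io.StringIO(text))
        assert len(table) == 3
        assert table.data["residue"].tolist() == [2, 3, 4]

    def test_row_with_blank_shift_dropped(self, caplog):
        text = "residue,HN,N\n2,8.1,120.5\n3,7.9,\n"
        with caplog.at_level("WARNING"):
            table = read_shift_table(io.StringIO(text))
        assert len(table) == 1
        assert "dropping" in caplog.text

    def test_unrecognizable_columns_raise(self):
        with pytest.raises(FormatError):
            read_shift_table(io.StringIO("a,b,c\n1,2,3\n"))

    def test_simulated_tables_round_trip(self, tmp_path):
        free, bound = simulate_shift_tables(
            n_residues=30, hotspot_ranges=((10, 12),), seed=4
        )
        path = tmp_path / "free.csv"
        write_shift_table(free, path)
        back = read_shift_table(path)
        pd.testing.assert_frame_equal(
            back.data[["residue", "delta_HN", "delta_N"]],
            free.data[["residue", "delta_HN", "delta_N"]],
        )


class TestComputeCsp:
    def test_analytic_values(self):
        free = _table([(1, "ALA", 8.0, 120.0), (2, "ALA", 8.0, 120.0),
                       (3, "ALA", 8.0, 120.0)])
        bound = _table([(1, "ALA", 8.0, 120.0), (2, "ALA", 8.1, 120.0),
                        (3, "ALA", 8.0, 120.5)], "bound")
        recs = {r.residue: r for r in compute_csp(free, bound).records}
        assert recs[1].delta_residue == pytest.approx(0.0)
        assert recs[2].delta_residue == pytest.approx(0.1 / np.sqrt(2), abs=1e-9)
        # the 1/5 nitrogen scaling makes 0.5 ppm in N equal 0.1 ppm in HN
        assert recs[3].delta_residue == pytest.approx(recs[2].delta_residue, abs=1e-9)

    def test_only_shared_residues_used_and_empty_intersection_raises(self):
        free = _table([(1, "ALA", 8.0, 120.0), (2, "ALA", 8.0, 120.0)])
        bound = _table([(2, "ALA", 8.2, 121.0), (3, "ALA", 8.0, 120.0)], "bound")
        summary = compute_csp(free, bound)
        assert [r.residue for r in summary.records] == [2]
        with pytest.raises(ValueError):
            compute_csp(free, _table([(9, "ALA", 8.0, 120.0)], "bound"))

    def test_sign_flip_invariance(self):
        free = _table([(1, "ALA", 8.0, 120.0)])
        up = compute_csp(free, _table([(1, "ALA", 8.2, 121.0)], "bound"))
        down = compute_csp(free, _table([(1, "ALA", 7.8, 119.0)], "bound"))
        assert up.records[0].delta_residue == pytest.approx(
            down.records[0].delta_residue, abs=1e-12
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_differences_scales_csp_but_not_regions(self, scale):
        rng = np.random.default_rng(0)
        residues = list(range(1, 41))
        base = [(i, "ALA", 8.0, 120.0) for i in residues]
        d_hn = rng.normal(0, 0.02, 40)
        d_hn[10:13] += 0.3  # hotspot
        free = _table(base)
        bound1 = _table([(i, "ALA", 8.0 + d, 120.0) for i, d in zip(residues, d_hn)],
                        "bound")
        bound2 = _table([(i, "ALA", 8.0 + scale * d, 120.0)
                         for i, d in zip(residues, d_hn)], "bound")
        s1 = compute_csp(free, bound1)
        s2 = compute_csp(free, bound2)
        assert s2.mean == pytest.approx(scale * s1.mean, rel=1e-9)
        assert perturbed_regions(s1.records, 3.0) == perturbed_regions(s2.records, 3.0)

    def test_threshold_nesting_3x_within_2x(self):
        free, bound = simulate_shift_tables(seed=8)
        summary = compute_csp(free, bound)
        assert set(summary.over_3x) <= set(summary.over_2x)


class TestPerturbedRegions:
    @staticmethod
    def _records(values, residues=None):
        residues = residues or list(range(1, len(values) + 1))
        return [CSPRecord(residue=r, d_HN=v, d_N=0.0, delta_residue=v)
                for r, v in zip(residues, values)]

    def test_all_below_threshold_gives_empty(self):
        assert perturbed_regions(self._records([0.1] * 10), 3.0) == []

    def test_two_separated_regions_called(self):
        values = [0.01] * 100
        for i in (18, 19):  # residues 19-20
            values[i] = 1.0
        for i in range(75, 85):  # residues 76-85
            values[i] = 1.0
        assert perturbed_regions(self._records(values), 3.0) == [(19, 20), (76, 85)]

    def test_missing_residue_gap_of_one_is_bridged(self):
        quiet = [0.01] * 30
        residues = [10, 12] + list(range(20, 48))  # residue 11 unassigned
        records = self._records([1.0, 1.0] + quiet[2:], residues=residues)
        assert perturbed_regions(records, 3.0) == [(10, 12)]
        # same gap with the intermediate residue present but quiet: no bridge
        residues = [10, 11, 12] + list(range(20, 48))
        records = self._records([1.0, 0.01, 1.0] + quiet[3:], residues=residues)
        assert perturbed_regions(records, 3.0) == [(10, 10), (12, 12)]

    def test_seeded_hotspot_recovered_exactly(self):
        free, bound = simulate_shift_tables(
            n_residues=100, hotspot_ranges=((40, 44),), hotspot_scale=4.0, seed=2
        )
        summary = compute_csp(free, bound)
        assert perturbed_regions(summary.records, 3.0) == [(40, 44)]
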