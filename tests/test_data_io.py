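"""Affinity-table ingestion, pKi transform, filtering, splitting, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agentmol.data_io import (
    AffinityDataset,
    LigandProteinPair,
    filter_pairs,
    ki_to_pki,
    pki_to_ki,
    read_pairs,
    split_dataset,
    summarize,
)


def _pair(smiles="CCO", protein="MKTAY", pki=5.0):
    return LigandProteinPair(smiles=smiles, protein_seq=protein, pki=pki)


class TestKiTransform:
    @pytest.mark.parametrize(
        "ki,expected", [(1.0, 9.0), (0.1, 10.0), (1e9, 0.0), (1000.0, 6.0)]
    )
    def test_reference_points(self, ki, expected):
        assert ki_to_pki(ki) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_ki_rejected(self, bad):
        with pytest.raises(ValueError):
            ki_to_pki(bad)

    @given(st.floats(min_value=0.0, max_value=12.0))
    def test_round_trip(self, p):
        assert ki_to_pki(pki_to_ki(p)) == pytest.approx(p, abs=1e-9)

    def test_monotone_decreasing(self):
        kis = np.logspace(-3, 9, 50)
        pkis = [ki_to_pki(k) for k in kis]
        assert all(a > b for a, b in zip(pkis, pkis[1:]))


class TestPairInvariants:
    def test_empty_fields_rejected(self):
        with pytest.raises(ValueError):
            LigandProteinPair(smiles="", protein_seq="MKT")
        with pytest.raises(ValueError):
            LigandProteinPair(smiles="CCO", protein_seq="")

    def test_inconsistent_affinities_rejected(self):
        with pytest.raises(ValueError):
            LigandProteinPair(smiles="CCO", protein_seq="MKT", ki_nM=1.0, pki=5.0)

    def test_pair_length(self):
        assert _pair(smiles="CCO", protein="MKTAY").pair_length == 8


class TestReadPairs:
    def test_identity_ingestion(self, tmp_path):
        f = tmp_path / "pairs.csv"
        f.write_text(
            "smiles,sequence,ki\nCCO,MKTAY,1.0\nCCN,AYYAY,10.0\nCCC,KKKAY,100.0\n"
        )
        ds = read_pairs(f, {"smiles": "smiles", "protein": "sequence", "ki": "ki"})
        assert len(ds) == 3
        assert ds[0].smiles == "CCO"
        assert ds[0].pki == pytest.approx(9.0)

    def test_missing_ki_row_dropped(self, tmp_path):
        f = tmp_path / "pairs.csv"
        f.write_text("smiles,sequence,ki\nCCO,MKTAY,1.0\nCCN,AYYAY,\nCCC,KKKAY,5\n")
        ds = read_pairs(f, {"smiles": "smiles", "protein": "sequence", "ki": "ki"})
        assert len(ds) == 2

    def test_missing_column_is_schema_error(self, tmp_path):
        f = tmp_path / "pairs.csv"
        f.write_text("smiles,ki\nCCO,1.0\n")
        with pytest.raises(KeyError, match="sequence"):
            read_pairs(f, {"smiles": "smiles", "protein": "sequence", "ki": "ki"})

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pairs(tmp_path / "absent.csv")

    def test_tsv_autodetected(self, tmp_path):
        f = tmp_path / "pairs.tsv"
        f.write_text("smiles\tprotein_seq\tki_nM\nCCO\tMKTAY\t1.0\n")
        assert len(read_pairs(f)) == 1


class TestFilterPairs:
    def test_hand_built_exclusions(self):
        ds = AffinityDataset(
            [
                _pair(pki=5.0),
                _pair(smiles="C" * 796, pki=5.0),  # pair_length 801
                _pair(pki=10.5),
                _pair(smiles="C" * 795, pki=10.0),  # both at the boundary
                _pair(pki=0.5),
            ]
        )
        kept = filter_pairs(ds)
        assert len(kept) == 3
        assert kept[1].pair_length == 800 and kept[1].pki == 10.0

    def test_idempotent(self):
        ds = AffinityDataset([_pair(pki=p) for p in (1.0, 5.0, 9.0, 10.5)])
        once = filter_pairs(ds)
        twice = filter_pairs(once)
        assert twice.pairs == once.pairs

    def test_missing_pki_is_state_error(self):
        ds = AffinityDataset([LigandProteinPair(smiles="CCO", protein_seq="MKT")])
        with pytest.raises(RuntimeError):
            filter_pairs(ds)


class TestSplitDataset:
    def _ds(self, n):
        return AffinityDataset([_pair(protein=f"MKTAY{i:04d}X", pki=5.0) for i in range(n)])

    def test_sizes_and_partition(self):
        ds = self._ds(10)
        train, val = split_dataset(ds, 0.7, seed=1)
        assert (len(train), len(val)) == (7, 3)
        key = lambda p: p.protein_seq
        assert sorted(map(key, train.pairs + val.pairs)) == sorted(map(key, ds.pairs))
        assert not {key(p) for p in train} & {key(p) for p in val}

    def test_deterministic_given_seed(self):
        ds = self._ds(20)
        a = split_dataset(ds, 0.7, seed=1)
        b = split_dataset(ds, 0.7, seed=1)
        assert a[0].pairs == b[0].pairs and a[1].pairs == b[1].pairs

    def test_different_seeds_differ(self):
        ds = self._ds(100)
        a, _ = split_dataset(ds, 0.7, seed=1)
        b, _ = split_dataset(ds, 0.7, seed=2)
        assert {p.protein_seq for p in a} != {p.protein_seq for p in b}

    @given(st.integers(min_value=2, max_value=60), st.integers(min_value=0, max_value=10))
    def test_partition_property(self, n, seed):
        ds = self._ds(n)
        train, val = split_dataset(ds, 0.7, seed=seed)
        assert len(train) == math.floor(0.7 * n)
        assert len(train) + len(val) == n

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_dataset(self._ds(5), 1.0, seed=0)


class TestSummarize:
    def test_single_pair_degenerate(self):
        ds = AffinityDataset([_pair(smiles="C" * 95, pki=5.0)])  # pair_length 100
        s = summarize(ds)
        assert s.mean_length == s.min_length == s.max_length == 100
        assert s.quartiles_length == (100, 100, 100)
        assert s.std_length == 0.0 and s.std_pki == 0.0
        assert s.mean_pki == 5.0

    def test_two_pair_mean(self):
        ds = AffinityDataset([_pair(pki=4.0), _pair(pki=6.0)])
        assert summarize(ds).mean_pki == pytest.approx(5.0)

    def test_five_pair_against_spreadsheet_oracle(self):
        # lengths 13,18,23,28,108 / pKi 2,4,5,7,9 -- statistics frozen from an
        # independent spreadsheet-convention computation (sample sd, linear
        # interpolation quartiles)
        pkis = [2.0, 4.0, 5.0, 7.0, 9.0]
        smiles = ["CCO", "CCCCCOON", "C" * 13, "C" * 18, "C" * 98]
        ds = AffinityDataset(
            [
                _pair(smiles=s, protein="MKTAYIAKQR", pki=p)
                for s, p in zip(smiles, pkis)
            ]
        )
        s = summarize(ds)
        assert s.n == 5
        assert s.mean_length == pytest.approx(38.0)
        assert s.std_length == pytest.approx(39.52847075, abs=1e-6)
        assert (s.min_length, s.max_length) == (13.0, 108.0)
        assert s.quartiles_length == pytest.approx((18.0, 23.0, 28.0))
        assert s.mean_pki == pytest.approx(5.4)
        assert s.std_pki == pytest.approx(2.701851217, abs=1e-6)
        assert s.quartiles_pki == pytest.approx((4.0, 5.0, 7.0))

    def test_filtered_summary_respects_bounds(self):
        rng = np.random.default_rng(0)
        ds = AffinityDataset(
            [
                _pair(smiles="C" * int(rng.integers(3, 900)), pki=float(rng.uniform(0, 12)))
                for _ in range(50)
            ]
        )
        s = summarize(filter_pairs(ds))
        assert s.max_length <= 800 and s.max_pki <= 10

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            summarize(AffinityDataset([]))
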