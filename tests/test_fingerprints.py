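import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpscreen.fingerprints import (
    BitFingerprint,
    FingerprintError,
    FingerprintType,
    SmilesParseError,
    compute_all_fingerprints,
    compute_fingerprint,
    enumerate_combinations,
    read_fingerprints_csv,
    read_matrix_container,
    read_smiles_file,
    stack,
    to_signed,
    write_fingerprints_csv,
    write_matrix_container,
)

BENZENE = "c1ccccc1"


class TestComputeFingerprint:
    def test_methane_has_no_torsion_paths(self):
        # a topological torsion needs a 4-heavy-atom path
        fp = compute_fingerprint("C", FingerprintType.TORSION)
        assert fp.popcount == 0

    def test_ethanol_morgan_regression(self):
        # popcount frozen from direct computation with this toolkit version
        fp = compute_fingerprint("CCO", FingerprintType.MORGAN)
        assert fp.popcount == 6
        assert fp.n_bits == 1024

    @pytest.mark.parametrize("fp_type", list(FingerprintType))
    def test_benzene_sets_bits_under_every_scheme(self, fp_type):
        fp = compute_fingerprint(BENZENE, fp_type)
        assert fp.popcount >= 1

    @pytest.mark.parametrize("fp_type", list(FingerprintType))
    def test_deterministic(self, fp_type):
        a = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", fp_type)
        b = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", fp_type)
        np.testing.assert_array_equal(a.bits, b.bits)

    def test_morgan_and_ecfp4_differ(self):
        smi = "CC(=O)Oc1ccccc1C(=O)O"
        a = compute_fingerprint(smi, FingerprintType.MORGAN)
        b = compute_fingerprint(smi, FingerprintType.ECFP4)
        assert not np.array_equal(a.bits, b.bits)

    def test_unparseable_smiles_raises_with_offender(self):
        with pytest.raises(SmilesParseError) as exc:
            compute_fingerprint("not_a_molecule((", FingerprintType.MORGAN)
        assert "not_a_molecule((" in str(exc.value)

    def test_unknown_type_and_small_nbits_rejected(self):
        with pytest.raises(FingerprintError):
            compute_fingerprint("CCO", "morgan")  # type: ignore[arg-type]
        with pytest.raises(FingerprintError):
            compute_fingerprint("CCO", FingerprintType.MORGAN, n_bits=32)

    def test_salt_stripping_keeps_largest_fragment(self):
        plain = compute_fingerprint("CCN", FingerprintType.MORGAN)
        salt = compute_fingerprint("CCN.Cl", FingerprintType.MORGAN)
        np.testing.assert_array_equal(plain.bits, salt.bits)


class TestSignedRecoding:
    def test_all_zero_maps_to_all_minus_one(self):
        fp = BitFingerprint(np.zeros(1024), FingerprintType.MORGAN)
        assert (to_signed(fp).values == -1).all()

    def test_all_one_maps_to_all_plus_one(self):
        fp = BitFingerprint(np.ones(1024), FingerprintType.MORGAN)
        assert (to_signed(fp).values == 1).all()

    def test_popcount_sum_identity(self, rng):
        bits = np.zeros(1024, dtype=np.uint8)
        bits[rng.choice(1024, 100, replace=False)] = 1
        signed = to_signed(BitFingerprint(bits, FingerprintType.RDKIT))
        assert signed.values.sum() == 2 * 100 - 1024 == -824

    @given(st.lists(st.integers(0, 1), min_size=64, max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_lossless(self, bits):
        fp = BitFingerprint(np.array(bits), FingerprintType.LAYERED)
        back = to_signed(fp).to_bits()
        np.testing.assert_array_equal(back.bits, fp.bits)


class TestStack:
    def _signed(self, smiles="c1ccc(O)cc1", types=None):
        return [
            to_signed(fp)
            for fp in compute_all_fingerprints(smiles, compound_id="x", types=types)
        ]

    def test_full_stack_is_7x1024(self):
        m = stack(self._signed())
        assert m.to_array().shape == (7, 1024)

    def test_rows_sorted_to_canonical_order(self):
        fps = self._signed(types=[FingerprintType.MORGAN, FingerprintType.RDKIT])
        m = stack(fps[::-1])
        assert m.fp_types == (FingerprintType.RDKIT, FingerprintType.MORGAN)

    def test_rows_preserve_content_exactly(self):
        fps = self._signed()
        m = stack(fps)
        for row, fp in zip(m.rows, fps):
            np.testing.assert_array_equal(row.values, fp.values)

    def test_duplicate_type_rejected(self):
        fp = self._signed(types=[FingerprintType.MORGAN, FingerprintType.RDKIT])[0]
        with pytest.raises(FingerprintError):
            stack([fp, fp])

    def test_mixed_compound_ids_rejected(self):
        a = to_signed(compute_fingerprint("CCO", FingerprintType.MORGAN, compound_id="a"))
        b = to_signed(compute_fingerprint("CCN", FingerprintType.RDKIT, compound_id="b"))
        with pytest.raises(FingerprintError):
            stack([a, b])


class TestEnumerateCombinations:
    def test_all_seven_types_give_120_subsets(self):
        combos = enumerate_combinations(FingerprintType.canonical())
        assert len(combos) == 2**7 - 7 - 1 == 120
        assert len(set(combos)) == 120
        for combo in combos:
            assert list(combo) == sorted(combo, key=lambda t: t.order)

    def test_two_types_give_one_subset(self):
        combos = enumerate_combinations([FingerprintType.MORGAN, FingerprintType.ECFP4])
        assert combos == [(FingerprintType.MORGAN, FingerprintType.ECFP4)]

    def test_three_types_give_four_subsets(self):
        types = [FingerprintType.RDKIT, FingerprintType.MORGAN, FingerprintType.TORSION]
        assert len(enumerate_combinations(types)) == 4

    def test_single_type_rejected(self):
        with pytest.raises(FingerprintError):
            enumerate_combinations([FingerprintType.MORGAN])


class TestIO:
    def test_fingerprint_csv_round_trip(self, tmp_path):
        fps = [
            compute_fingerprint("CCO", FingerprintType.MORGAN, compound_id="a"),
            compute_fingerprint("CCN", FingerprintType.RDKIT, compound_id="b"),
        ]
        path = tmp_path / "fps.csv"
        write_fingerprints_csv(fps, path)
        back = read_fingerprints_csv(path, signed=False)
        assert [f.compound_id for f in back] == ["a", "b"]
        np.testing.assert_array_equal(back[0].bits, fps[0].bits)

    def test_matrix_container_round_trip(self, tmp_path, rng):
        mat = rng.choice([-1, 1], size=(5, 2, 64)).astype(np.int8)
        types = [FingerprintType.MORGAN, FingerprintType.TORSION]
        write_matrix_container([f"c{i}" for i in range(5)], mat, types,
                               tmp_path / "m.npy")
        back, ids, back_types = read_matrix_container(tmp_path / "m.npy")
        np.testing.assert_array_equal(back, mat)
        assert ids == [f"c{i}" for i in range(5)]
        assert back_types == types

    def test_smiles_file_reader(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\tfirst\nCCN\n# comment\n")
        df = read_smiles_file(p)
        assert list(df["smiles"]) == ["CCO", "CCN"]
        assert df["id"][0] == "first"
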