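import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidostab.catalogue import feature_catalogue
from acidostab.features import (
    ProteinFeaturizer,
    category_features,
    compute_features,
    protparam_indices,
)
from acidostab.io import ProteinRecord
from acidostab.tables import STANDARD_AA

sequences = st.text(alphabet=STANDARD_AA, min_size=1, max_size=60)


class TestCatalogue:
    def test_total_and_subset_sizes(self):
        cat = feature_catalogue()
        assert len(cat) == 889
        assert len(cat.native_names) == 871
        assert len(cat.external_names) == 18

    def test_group_sizes_sum_to_total(self):
        sizes = feature_catalogue().group_sizes()
        assert sum(sizes.values()) == 889
        assert sorted(sizes.values(), reverse=True) == sorted(
            [1, 40, 800, 8, 12, 2, 1, 1, 2, 2, 1, 1, 6, 4, 6, 1, 1], reverse=True
        )

    def test_dipeptide_group_size(self):
        sizes = feature_catalogue().group_sizes()
        assert sizes["dipeptide counts and compositions"] == 800

    def test_names_unique_and_ordered(self):
        cat = feature_catalogue()
        assert len(set(cat.names)) == len(cat.names)
        assert cat.names[0] == "length"


class TestComputeFeatures:
    def test_homopolymer(self):
        f = compute_features(ProteinRecord("a", "AAA"))
        assert f["x_A"] == 1.0
        assert f["c_AA"] == 2
        assert f["x_AA"] == 1.0

    def test_sulfur_and_net_charge(self):
        f = compute_features(ProteinRecord("a", "ACDC"))
        assert f["c_sulfur"] == 2  # two Cys, no Met
        assert f["c_net_charge"] == -1

    def test_gravy_of_poly_alanine(self):
        f = compute_features(ProteinRecord("a", "AAA"))
        assert f["gravy"] == pytest.approx(1.8)

    def test_external_values_filled_or_nan(self):
        f = compute_features(ProteinRecord("a", "ACDEF"), external={"rsa_mean": 0.4})
        assert f["rsa_mean"] == 0.4
        assert math.isnan(f["zfit_mean"])

    def test_unknown_external_name_rejected(self):
        with pytest.raises(ValueError, match="unknown external"):
            compute_features(ProteinRecord("a", "ACDEF"), external={"x_A": 1.0})

    def test_ambiguity_skipped_in_numerators_not_length(self):
        f = compute_features(ProteinRecord("a", "AXA"))
        assert f["length"] == 3
        assert f["c_A"] == 2
        assert f["x_A"] == pytest.approx(2 / 3)
        assert f["c_AA"] == 0  # the A-X-A dipeptides both touch X

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seq=sequences)
    def test_composition_sums_and_count_consistency(self, seq):
        rec = ProteinRecord("s", seq)
        f = compute_features(rec)
        aa_sum = sum(f[f"x_{a}"] for a in STANDARD_AA)
        assert aa_sum == pytest.approx(1.0, abs=1e-9)
        if rec.length > 1:
            dp_sum = sum(v for k, v in f.items() if k.startswith("x_") and len(k) == 4)
            assert dp_sum == pytest.approx(1.0, abs=1e-9)
        for a in STANDARD_AA:
            assert f[f"c_{a}"] == pytest.approx(f[f"x_{a}"] * rec.length)
        assert all(0 <= f[f"x_{a}"] <= 1 for a in STANDARD_AA)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(s=sequences, t=sequences)
    def test_concatenation_adds_counts_plus_boundary(self, s, t):
        fs = compute_features(ProteinRecord("s", s))
        ft = compute_features(ProteinRecord("t", t))
        fst = compute_features(ProteinRecord("st", s + t))
        for a in STANDARD_AA:
            assert fst[f"c_{a}"] == fs[f"c_{a}"] + ft[f"c_{a}"]
        boundary = s[-1] + t[0]
        dipep_names = [k for k in fst if k.startswith("c_") and len(k) == 4]
        for name in dipep_names:
            expected = fs[name] + ft[name] + (1 if name == f"c_{boundary}" else 0)
            assert fst[name] == expected

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet=STANDARD_AA, min_size=2, max_size=40), seed=st.integers(0, 10))
    def test_permutation_preserves_single_residue_features(self, seq, seed):
        import random

        chars = list(seq)
        random.Random(seed).shuffle(chars)
        f1 = compute_features(ProteinRecord("a", seq))
        f2 = compute_features(ProteinRecord("b", "".join(chars)))
        for a in STANDARD_AA:
            assert f1[f"c_{a}"] == f2[f"c_{a}"]
        assert f1["c_net_charge"] == f2["c_net_charge"]
        assert f1["gravy"] == pytest.approx(f2["gravy"])
        assert f1["aliphatic_index"] == pytest.approx(f2["aliphatic_index"])


class TestProtparamIndices:
    def test_poly_alanine_aliphatic_index(self):
        idx = protparam_indices(ProteinRecord("a", "AAAA"))
        assert idx["aliphatic_index"] == pytest.approx(100.0)

    def test_poly_valine_aliphatic_index(self):
        idx = protparam_indices(ProteinRecord("v", "VVVV"))
        assert idx["aliphatic_index"] == pytest.approx(290.0)

    def test_instability_threshold_rule(self):
        idx = protparam_indices(ProteinRecord("a", "ACDEFGHIKLMNPQRSTVWY"))
        assert (idx["instability_class"] == 1.0) == (idx["instability_index"] > 40)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            protparam_indices(ProteinRecord("x", "XXX"))

    def test_acidic_protein_has_low_pi(self):
        acidic = protparam_indices(ProteinRecord("d", "DDDDDDDDDD"))
        basic = protparam_indices(ProteinRecord("k", "KKKKKKKKKK"))
        assert acidic["pI"] < 5 < basic["pI"]


class TestCategoryFeatures:
    def test_small_residues(self):
        f = category_features(ProteinRecord("a", "TD"))
        assert f["c_small"] == 2
        assert f["x_small"] == 1.0

    def test_tiny_residues(self):
        f = category_features(ProteinRecord("a", "GASP"))
        assert f["c_tiny"] == 4
        assert f["x_tiny"] == 1.0

    def test_aromatic_and_hbond(self):
        f = category_features(ProteinRecord("a", "FHYW"))
        assert f["x_aromatic"] == 1.0
        assert f["c_hbond"] == 3  # H, Y, W side chains; Phe cannot


class TestProteinFeaturizer:
    def test_native_matrix_shape_and_columns(self):
        records = [ProteinRecord("a", "ACDEF"), ProteinRecord("b", "GHIKL")]
        X = ProteinFeaturizer().fit(records).transform(records)
        assert X.shape == (2, 871)
        assert not X.isna().any().any()

    def test_explicit_subset(self):
        records = [ProteinRecord("a", "ACDEF")]
        X = ProteinFeaturizer(subset=["x_A", "gravy"]).fit(records).transform(records)
        assert list(X.columns) == ["x_A", "gravy"]

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValueError):
            ProteinFeaturizer(subset=["nope"]).fit([])
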