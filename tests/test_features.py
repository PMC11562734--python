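import numpy as np
import pytest
from rdkit import Chem

from iluq.chem import Conditions, parse_ion_pair
from iluq.features import (
    ATOM_FEATURE_DIM,
    BinaryFingerprintFeaturizer,
    CountFingerprintFeaturizer,
    DescriptorFeaturizer,
    FeatureVector,
    GraphFeaturizer,
    ImageFeaturizer,
    RenderError,
    attach_conditions,
    binary_fingerprint,
    build_graph,
    count_fingerprint,
    descriptor_vector,
    render_image,
    _ELEMENTS,
)


class TestFingerprints:
    def test_deterministic(self, tma_acetate):
        a = count_fingerprint(tma_acetate)
        b = count_fingerprint(tma_acetate)
        np.testing.assert_array_equal(a.values, b.values)

    def test_binary_entries_are_bits(self, tma_acetate):
        v = binary_fingerprint(tma_acetate).values
        assert set(np.unique(v)) <= {0.0, 1.0}

    def test_counts_nonnegative_integers(self, tma_acetate):
        v = count_fingerprint(tma_acetate).values
        assert np.all(v >= 0)
        np.testing.assert_array_equal(v, np.round(v))

    def test_binary_equals_clipped_counts(self, small_library):
        """min(count, 1) elementwise reproduces the binary fingerprint."""
        cations, anions = small_library
        for c, a in zip(cations[:5], anions[:5]):
            pair = parse_ion_pair(f"{c}.{a}", "t")
            cnt = count_fingerprint(pair).values
            bin_ = binary_fingerprint(pair).values
            np.testing.assert_array_equal(np.minimum(cnt, 1.0), bin_)

    def test_count_vectors_distinguish_homologs(self):
        a = parse_ion_pair("CC[N+](C)(C)C.[Cl-]", "a")
        b = parse_ion_pair("C[N+](C)(C)C.[Cl-]", "b")
        va = count_fingerprint(a).values
        vb = count_fingerprint(b).values
        assert np.any(va != vb)

    def test_disconnected_duplicate_doubles_counts(self):
        """Two copies of a fragment double every count bucket it sets."""
        f = CountFingerprintFeaturizer()
        one = f._one(Chem.MolFromSmiles("CCO"))
        two = f._one(Chem.MolFromSmiles("CCO.CCO"))
        np.testing.assert_array_equal(two, 2 * one)

    def test_concatenation_keeps_ion_identity(self):
        ab = parse_ion_pair("C[N+](C)(C)C.CC(=O)[O-]", "ab")
        v = count_fingerprint(ab, n_bits=512).values
        assert len(v) == 1024
        # swapping which ion carries a substructure changes the half it lands in
        assert np.any(v[:512] != v[512:])


class TestDescriptors:
    def test_molecular_weight_oracle(self, ammonium_chloride):
        """MW coordinates equal hand sums from standard atomic masses."""
        v = descriptor_vector(ammonium_chloride).values
        n_desc = len(v) // 2
        mw_cation, mw_anion = v[0], v[n_desc]
        assert mw_cation == pytest.approx(14.007 + 4 * 1.008, abs=0.01)
        assert mw_anion == pytest.approx(35.45, abs=0.01)

    def test_heavy_atom_count(self):
        pair = parse_ion_pair("C[N+](C)(C)C.[Cl-]", "t")
        v = descriptor_vector(pair).values
        names = DescriptorFeaturizer().feature_names
        assert v[names.index("cation:HeavyAtomCount")] == 5
        assert v[names.index("anion:HeavyAtomCount")] == 1

    def test_deterministic_and_finite(self, tma_acetate):
        a = descriptor_vector(tma_acetate).values
        b = descriptor_vector(tma_acetate).values
        np.testing.assert_array_equal(a, b)
        assert np.all(np.isfinite(a))


class TestImages:
    def test_declared_canvas_dimensions(self, tma_acetate):
        img = render_image(tma_acetate, height=64, width=64, channels=1)
        assert img.pixels.shape == (64, 64, 1)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_deterministic_without_augmentation(self, tma_acetate):
        a = render_image(tma_acetate)
        b = render_image(tma_acetate)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_rendered_pair_is_not_blank(self, tma_acetate):
        img = render_image(tma_acetate)
        assert img.pixels.sum() > 0.0

    def test_rotation_augmentation_gives_four_images(self, tma_acetate):
        imgs = render_image(tma_acetate, augment="rotations")
        assert len(imgs) == 4

    def test_too_small_canvas_is_render_error(self, tma_acetate):
        with pytest.raises(RenderError):
            ImageFeaturizer(height=8, width=8).render(tma_acetate)


class TestGraphs:
    def test_node_count_equals_heavy_atoms_for_random_pairs(self, small_library):
        """Graph nodes enumerate exactly the heavy atoms of both ions."""
        cations, anions = small_library
        rng = np.random.default_rng(5)
        for _ in range(50):
            c = cations[rng.integers(len(cations))]
            a = anions[rng.integers(len(anions))]
            pair = parse_ion_pair(f"{c}.{a}", "t")
            g = build_graph(pair)
            expected = Chem.MolFromSmiles(pair.smiles).GetNumAtoms()
            assert g.n_nodes == expected

    def test_no_edge_crosses_the_component_boundary(self, small_library):
        cations, anions = small_library
        pair = parse_ion_pair(f"{cations[0]}.{anions[0]}", "t")
        g = build_graph(pair)
        for i, j in g.edges:
            assert g.component_tag[i] == g.component_tag[j]

    def test_three_heavy_atom_ion_structure(self):
        pair = parse_ion_pair("CC[NH3+].[Cl-]", "t")
        g = build_graph(pair)
        cation_nodes = np.nonzero(g.component_tag == 0)[0]
        assert len(cation_nodes) == 3
        cation_edges = [e for e in g.edges if g.component_tag[e[0]] == 0]
        assert len(cation_edges) == 2

    def test_formal_charge_node_feature(self, ammonium_chloride):
        g = build_graph(ammonium_chloride)
        charge_col = len(_ELEMENTS) + 1 + 1
        n_idx = np.nonzero(g.node_features[:, _ELEMENTS.index("N")] == 1)[0]
        assert g.node_features[n_idx[0], charge_col] == 1.0

    def test_feature_dimensions(self, tma_acetate):
        g = build_graph(tma_acetate)
        assert g.node_features.shape[1] == ATOM_FEATURE_DIM
        assert g.edge_features.shape[0] == g.edges.shape[0]


class TestAttachConditions:
    def test_viscosity_adds_temperature_only(self, tma_acetate):
        fv = count_fingerprint(tma_acetate)
        out = attach_conditions(fv, Conditions(), "viscosity")
        assert len(out) == len(fv) + 1

    def test_co2_capacity_adds_both(self, tma_acetate):
        fv = count_fingerprint(tma_acetate)
        out = attach_conditions(fv, Conditions(), "co2_capacity")
        assert len(out) == len(fv) + 2

    def test_condition_free_property_is_identity(self, tma_acetate):
        fv = count_fingerprint(tma_acetate)
        out = attach_conditions(fv, Conditions(), "refractive_index")
        np.testing.assert_array_equal(out.values, fv.values)

    def test_image_input_is_contract_error(self, tma_acetate):
        img = render_image(tma_acetate)
        with pytest.raises(TypeError):
            attach_conditions(img, Conditions(), "viscosity")

    def test_standard_conditions_map_to_zero(self, tma_acetate):
        fv = count_fingerprint(tma_acetate)
        out = attach_conditions(fv, Conditions(), "co2_capacity")
        np.testing.assert_allclose(out.values[-2:], 0.0)
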