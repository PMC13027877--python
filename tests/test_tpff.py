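"""Triple-path fusion: simplex coefficients, path semantics, residual
asymmetry and linear-combination oracles."""

import numpy as np
import pytest

from ltpnet import nn
from ltpnet.exceptions import ShapeError
from ltpnet.nn import ops
from ltpnet.tpff import TPFF, normalize_coefficients
from oracles import zero_convs


class TestCoefficients:
    def test_default_initialization(self):
        c = normalize_coefficients(np.log([0.4, 0.2, 0.4]))
        assert c.alpha == pytest.approx(0.4, abs=1e-12)
        assert c.beta == pytest.approx(0.2, abs=1e-12)
        assert c.gamma == pytest.approx(0.4, abs=1e-12)

    def test_equal_logits_uniform(self):
        c = normalize_coefficients([1.7, 1.7, 1.7])
        assert c.as_array() == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_sum_to_one_any_logits(self, rng):
        for _ in range(20):
            c = normalize_coefficients(rng.normal(size=3) * 5)
            assert abs(c.as_array().sum() - 1.0) < 1e-12
            assert np.all(c.as_array() > 0.0)

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            normalize_coefficients([np.inf, 0.0, 0.0])

    def test_module_default_coefficients(self):
        tpff = TPFF(8)
        c = tpff.coefficients()
        assert c.as_array() == pytest.approx([0.4, 0.2, 0.4], abs=1e-12)


class TestPaths:
    def test_common_path_cancellation(self, random_fmap):
        tpff = TPFF(8)
        zero_convs(tpff.ca_cp)
        a = random_fmap((1, 8, 4, 4))
        out = tpff.common_path(a, nn.Tensor(-a.data))
        assert np.array_equal(out.data, np.zeros((1, 8, 4, 4)))

    def test_common_path_symmetric(self, random_fmap):
        tpff = TPFF(8)
        a, b = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        assert np.array_equal(tpff.common_path(a, b).data, tpff.common_path(b, a).data)

    def test_common_path_composition(self, random_fmap):
        tpff = TPFF(8)
        a, b = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        fcp = ops.add(a, b)
        manual = ops.add(tpff.ca_cp(fcp), fcp)
        assert np.allclose(tpff.common_path(a, b).data, manual.data, atol=1e-6)

    def test_saliency_zero_high_keeps_low(self, random_fmap):
        tpff = TPFF(8)
        zero_convs(tpff.ca_sp)
        a = random_fmap((1, 8, 4, 4))
        out = tpff.saliency_path(a, nn.Tensor(np.zeros((1, 8, 4, 4))))
        assert np.array_equal(out.data, a.data)

    def test_saliency_residual_uses_low_input(self, random_fmap):
        tpff = TPFF(8)
        a, b = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        fsp = ops.mul(a, b)
        manual = ops.add(tpff.ca_sp(fsp), a)
        assert np.allclose(tpff.saliency_path(a, b).data, manual.data, atol=1e-6)

    def test_difference_equal_inputs_keeps_low(self, random_fmap):
        tpff = TPFF(8)
        zero_convs(tpff.ca_dp)
        a = random_fmap((1, 8, 4, 4))
        assert np.array_equal(tpff.difference_path(a, a).data, a.data)

    def test_difference_core_antisymmetry(self, random_fmap):
        a, b = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        fdp_ab = ops.sub(a, b)
        fdp_ba = ops.sub(b, a)
        assert np.array_equal(fdp_ab.data, -fdp_ba.data)

    def test_difference_composition(self, random_fmap):
        tpff = TPFF(8)
        a, b = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        fdp = ops.sub(a, b)
        manual = ops.add(tpff.ca_dp(fdp), a)
        assert np.allclose(tpff.difference_path(a, b).data, manual.data, atol=1e-6)

    def test_extent_mismatch_rejected(self, random_fmap):
        tpff = TPFF(8)
        with pytest.raises(ShapeError):
            tpff.common_path(random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 8, 8)))


class TestFusion:
    def test_cp_only_masks_other_paths(self, random_fmap):
        tpff = TPFF(8, enabled_paths=("cp",))
        hi, lo = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        flow, fhigh = tpff.project(hi, lo)
        assert np.allclose(tpff(hi, lo).data, tpff.common_path(flow, fhigh).data,
                           atol=1e-12)
        assert tpff.coefficients().as_array() == pytest.approx([1.0, 0.0, 0.0])

    def test_shape(self, random_fmap):
        tpff = TPFF(64)
        out = tpff(random_fmap((1, 64, 16, 16)), random_fmap((1, 64, 16, 16)))
        assert out.shape == (1, 64, 16, 16)

    def test_linear_combination_oracle(self, random_fmap):
        tpff = TPFF(8)
        hi, lo = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        flow, fhigh = tpff.project(hi, lo)
        c = tpff.coefficients()
        manual = (c.alpha * tpff.common_path(flow, fhigh).data
                  + c.beta * tpff.saliency_path(flow, fhigh).data
                  + c.gamma * tpff.difference_path(flow, fhigh).data)
        assert np.allclose(tpff(hi, lo).data, manual, atol=1e-6)

    @pytest.mark.parametrize("paths", [("cp",), ("cp", "sp"), ("cp", "sp", "dp")])
    def test_path_ablation_configurations(self, random_fmap, paths):
        tpff = TPFF(8, enabled_paths=paths)
        out = tpff(random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4)))
        assert out.shape == (1, 8, 4, 4)
        w = tpff.coefficients().as_array()
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.count_nonzero(w) == len(paths)

    def test_linearity_in_coefficients(self, random_fmap):
        # with fixed inputs the output is an exact linear functional of
        # (alpha, beta, gamma): verify superposition over two settings
        nn.manual_seed(3)
        tpff = TPFF(8)
        hi, lo = random_fmap((1, 8, 4, 4)), random_fmap((1, 8, 4, 4))
        flow, fhigh = tpff.project(hi, lo)
        paths = np.stack([
            tpff.common_path(flow, fhigh).data,
            tpff.saliency_path(flow, fhigh).data,
            tpff.difference_path(flow, fhigh).data,
        ])
        for logits in ([0.0, 0.0, 0.0], [1.0, -1.0, 0.5]):
            tpff.logits.data[...] = logits
            w = tpff.coefficients().as_array()
            expected = np.tensordot(w, paths, axes=1)
            assert np.allclose(tpff(hi, lo).data, expected, atol=1e-6)

    def test_cp_cannot_be_disabled(self):
        with pytest.raises(ValueError):
            TPFF(8, enabled_paths=("sp", "dp"))
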