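import numpy as np
import pandas as pd
import pytest

import genocam as gc
from genocam.dataset import ValidationError
from genocam.nn import ModelConfig
from genocam.screening import _cam_from_activations


class TestGradcamMap:
    def test_hand_computed_single_conv_toy(self):
        """One conv stage with hand-set weights on a 4x4 input.

        With all-ones 3x3 kernels and zero bias, channel 0 doubled, the logit
        gradient fixes alpha analytically; the map must equal
        ReLU(sum_k alpha_k A^k) computed by hand.
        """
        a3 = np.zeros((2, 2, 2))
        a3[..., 0] = [[1.0, 2.0], [0.5, 0.0]]
        a3[..., 1] = [[0.0, 1.0], [3.0, 1.0]]
        d_a3 = np.zeros((2, 2, 2))
        d_a3[..., 0] = 0.4   # alpha_0 = 0.4
        d_a3[..., 1] = -0.2  # alpha_1 = -0.2
        cam = _cam_from_activations(a3, d_a3, out_side=2)
        expected = np.maximum(0.4 * a3[..., 0] - 0.2 * a3[..., 1], 0.0)
        assert np.allclose(cam, expected)

    def test_upsampling_to_input_side(self, tiny_model):
        model, x, _, _ = tiny_model
        cam = gc.gradcam(model, x[0], target_class=gc.CASE)
        assert cam.grid.shape == (10, 10)
        assert (cam.grid >= 0).all()

    def test_constant_zero_activations_give_zero_map(self):
        cam = _cam_from_activations(np.zeros((3, 3, 4)), np.ones((3, 3, 4)), 6)
        assert (cam == 0).all()

    def test_nonnegative_for_random_inputs(self, tiny_model):
        model, x, _, _ = tiny_model
        rng = np.random.default_rng(0)
        for i in rng.integers(0, len(x), 5):
            assert (gc.gradcam(model, x[i]).grid >= 0).all()

    def test_invalid_class_rejected(self, tiny_model):
        model, x, _, _ = tiny_model
        with pytest.raises(ValidationError):
            gc.gradcam(model, x[0], target_class=7)


class TestAccumulate:
    def test_single_predicted_case_equals_its_map(self, tiny_model):
        model, x, _, _ = tiny_model
        preds = model.predict(x)
        i = int(np.flatnonzero(preds == gc.CASE)[0])
        acc = gc.accumulate_cams(model, x[i : i + 1])
        assert np.allclose(acc, gc.gradcam(model, x[i]).grid)

    def test_duplicated_case_doubles(self, tiny_model):
        model, x, _, _ = tiny_model
        i = int(np.flatnonzero(model.predict(x) == gc.CASE)[0])
        once = gc.accumulate_cams(model, x[i : i + 1])
        twice = gc.accumulate_cams(model, np.stack([x[i], x[i]]))
        assert np.allclose(twice, 2 * once)

    def test_predicted_controls_contribute_nothing(self, tiny_model):
        model, x, _, _ = tiny_model
        preds = model.predict(x)
        cases = x[preds == gc.CASE]
        mixed = gc.accumulate_cams(model, x)
        only_cases = gc.accumulate_cams(model, cases)
        assert np.allclose(mixed, only_cases)

    def test_no_predicted_cases_errors(self, tiny_model):
        model, x, y, _ = tiny_model
        controls_only = x[model.predict(x) == gc.CONTROL]
        with pytest.raises(ValidationError, match="predicted"):
            gc.accumulate_cams(model, controls_only)


class TestNormalizeWeights:
    def test_min_max(self):
        grid, flag = gc.normalize_weights(np.array([[0.0, 2.0], [4.0, 2.0]]))
        assert np.allclose(grid, [[0.0, 0.5], [1.0, 0.5]])
        assert not flag

    def test_constant_grid_degenerates_to_ones(self):
        grid, flag = gc.normalize_weights(np.full((3, 3), 7.0))
        assert (grid == 1.0).all() and flag

    def test_range_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g, _ = gc.normalize_weights(rng.random((5, 5)) * 100)
            assert g.min() >= 0.0 and g.max() <= 1.0


class TestPixelWeightsToSnps:
    def test_identity_on_full_grid(self):
        lay = gc.layout_end_to_end(4, 2)
        grid = np.array([[0.1, 0.2], [0.3, 0.4]])
        assert np.allclose(gc.pixel_weights_to_snps(grid, lay), [0.1, 0.2, 0.3, 0.4])

    def test_padding_cells_dropped(self):
        lay = gc.layout_end_to_end(2000, 45)
        w = gc.pixel_weights_to_snps(np.ones((45, 45)), lay)
        assert len(w) == 2000

    def test_side_mismatch_errors(self):
        lay = gc.layout_end_to_end(4, 2)
        with pytest.raises(ValidationError):
            gc.pixel_weights_to_snps(np.ones((3, 3)), lay)

    def test_equivariant_under_layout_permutation(self):
        lay = gc.layout_end_to_end(6, 3)
        grid = np.arange(9, dtype=float).reshape(3, 3)
        perm = np.array([3, 1, 4, 0, 5, 2])
        permuted = gc.LayoutMap(side=3, entries=lay.entries[perm],
                                padding_mask=lay.padding_mask)
        w = gc.pixel_weights_to_snps(grid, lay)
        wp = gc.pixel_weights_to_snps(grid, permuted)
        assert np.allclose(wp, w[perm])


class TestSelectTop:
    def test_2000_at_5pct_gives_100(self):
        w = np.random.default_rng(0).random(2000)
        assert len(gc.select_top(w, 0.05)) == 100

    def test_ceil_rule(self):
        assert len(gc.select_top(np.ones(41), 0.05)) == 3  # ceil(2.05)

    def test_ties_break_by_index(self):
        sel = gc.select_top(np.ones(10), 0.5)
        assert sel.tolist() == [0, 1, 2, 3, 4]

    def test_fraction_one_returns_all_ranked(self):
        w = np.array([0.1, 0.9, 0.5])
        assert gc.select_top(w, 1.0).tolist() == [1, 2, 0]

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            gc.select_top(np.ones(4), 0.0)


class TestAnnotateAndScore:
    def _annotation(self):
        return pd.DataFrame(
            {"snp_id": ["s0", "s1", "s2"], "gene_symbol": ["G1", "G1", "G2"]}
        )

    def test_ratio_by_definition(self):
        rep = gc.annotate_and_score(
            ["s0", "s1", "s2", "s3"], np.array([0.9, 0.8, 0.7, 0.1]),
            np.array([0, 1, 2]), self._annotation(), {"G1"},
        )
        assert rep.genes == ["G1", "G2"]
        assert rep.risk_gene_ratio == pytest.approx(0.5)

    def test_unannotated_selected_snp_kept_in_snp_list(self):
        rep = gc.annotate_and_score(
            ["s0", "s9"], np.array([0.9, 0.8]), np.array([0, 1]),
            self._annotation(), {"G1"},
        )
        assert "s9" not in rep.snp_genes
        frame = rep.to_frame()
        assert bool(frame.loc[frame.snp_id == "s9", "selected"].iloc[0])

    def test_no_annotated_selection_ratio_not_applicable(self):
        rep = gc.annotate_and_score(
            ["sX"], np.array([1.0]), np.array([0]), self._annotation(), {"G1"},
        )
        assert rep.risk_gene_ratio is None

    def test_empty_annotation_warns_and_empties(self):
        rep = gc.annotate_and_score(
            ["s0"], np.array([1.0]), np.array([0]),
            pd.DataFrame(columns=["snp_id", "gene_symbol"]), {"G1"},
        )
        assert rep.genes == [] and rep.risk_gene_ratio is None

    def test_report_files_round_trip(self, tmp_path):
        rep = gc.annotate_and_score(
            ["s0", "s1", "s2", "s3"], np.array([0.9, 0.8, 0.7, 0.1]),
            np.array([0, 1, 2]), self._annotation(), {"G1", "G3"},
        )
        rep.write(tmp_path / "report.tsv", tmp_path / "summary.json")
        back = pd.read_csv(tmp_path / "report.tsv", sep="\t")
        assert back["selected"].sum() == 3
        import json

        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["n_genes"] == 2 and summary["risk_gene_ratio"] == 0.5


class TestScreenPipeline:
    def test_screen_is_deterministic_and_sized(self, tiny_model):
        model, x, y, layout = tiny_model
        rep = gc.screen(model, x, layout, [f"s{i}" for i in range(100)])
        assert len(rep.selected) == 5  # ceil(0.05 * 100)
        rep2 = gc.screen(model, x, layout, [f"s{i}" for i in range(100)])
        assert np.array_equal(rep.selected, rep2.selected)
        assert np.allclose(rep.weights, rep2.weights)


def _engineered_model():
    """A model with hand-set weights whose case logit reads one image region.

    Delta kernels pass the red channel (aa genotype intensity) through all
    three conv stages unchanged; the dense layer sums the pooled map with
    positive weight into the case logit. Grad-CAM must therefore highlight
    exactly where minor homozygotes sit.
    """
    cfg = ModelConfig(input_side=16, input_channels=3, conv_filters=(1, 1, 1),
                      dropout_rate=0.0, seed=0)
    model = gc.build_model(cfg, gc.HyperParams(filter_size=3))
    for name, cin in (("w1", 3), ("w2", 1), ("w3", 1)):
        w = np.zeros((3, 3, cin, 1))
        w[1, 1, 0, 0] = 1.0  # delta on channel 0 (red)
        model.params[name] = w
        model.params[name.replace("w", "b")] = np.zeros(1)
    flat = model.spatial_sizes[-1] ** 2  # 2x2 pooled map
    wd = np.zeros((flat, 2))
    wd[:, 1] = 1.0  # case logit = sum of pooled red intensities
    model.params["wd"] = wd
    model.params["bd"] = np.array([0.1, 0.0])  # control wins on blank images
    return model


class TestScreeningRecoversEngineeredSignal:
    def test_top_fraction_recovers_the_risk_block(self):
        """End-to-end screening on a model with known attribution structure.

        Case images carry aa genotypes in one 4x4 SNP block; the screening
        stage must place that block's SNPs at the top of the ranking.
        """
        model = _engineered_model()
        layout = gc.layout_end_to_end(256, 16)
        risk_cells = [(r, c) for r in range(4, 8) for c in range(4, 8)]
        risk_idx = {r * 16 + c for r, c in risk_cells}
        images = []
        for i in range(6):
            codes = np.zeros(256, dtype=int)
            for j in risk_idx:
                codes[j] = 2  # aa -> red pixels in the risk block
            images.append(gc.encode_cc(codes, layout, f"case{i}", 1))
        x, _ = gc.stack_images(images)
        assert (model.predict(x) == gc.CASE).all()
        rep = gc.screen(model, x, layout, [f"s{i}" for i in range(256)],
                        fraction=16 / 256)
        recovered = len(set(rep.selected.tolist()) & risk_idx)
        assert recovered >= 12  # bilinear upsampling may blur the block edge

    def test_gene_ratio_beats_permutation_baseline(self):
        """Weights concentrated on risk-gene SNPs yield a ratio above chance.

        Synthetic weights (not a trained model) isolate the scoring logic:
        risk SNPs get boosted weights, genes are assigned so risk SNPs map to
        reference genes, and the observed risk-gene ratio must beat the mean
        ratio under weight shuffling.
        """
        rng = np.random.default_rng(0)
        n = 200
        risk = np.zeros(n, dtype=bool)
        risk[rng.choice(n, 20, replace=False)] = True
        weights = rng.random(n) * 0.3
        weights[risk] += 0.7
        snp_ids = [f"s{i}" for i in range(n)]
        ann = pd.DataFrame({
            "snp_id": snp_ids,
            "gene_symbol": [f"RG{i // 2}" if risk[i] else f"NG{i // 2}" for i in range(n)],
        })
        reference = {g for g in ann.gene_symbol if g.startswith("RG")}

        def ratio_of(w):
            sel = gc.select_top(w, 0.05)
            rep = gc.annotate_and_score(snp_ids, w, sel, ann, reference)
            return rep.risk_gene_ratio if rep.risk_gene_ratio is not None else 0.0

        observed = ratio_of(weights)
        baseline = np.mean([ratio_of(rng.permutation(weights)) for _ in range(50)])
        assert observed == 1.0  # every top-5% SNP is a risk SNP by construction
        assert observed > baseline + 0.5
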