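import numpy as np
import pytest

import genocam as gc


@pytest.fixture(scope="session")
def small_dataset() -> gc.GenotypeDataset:
    """600 samples x 100 SNPs with 20 planted risk SNPs (rr_het = 2)."""
    spec = gc.SimulationSpec(
        n_cases=300, n_controls=300, n_null_snps=80, n_risk_snps=20,
        rr_het=2.0, seed=11,
    )
    return gc.simulate_dataset(spec)


@pytest.fixture(scope="session")
def null_dataset() -> gc.GenotypeDataset:
    """No-effect dataset at fixed MAF 0.3 for calibration checks."""
    spec = gc.SimulationSpec(
        n_cases=1000, n_controls=1000, n_null_snps=2000, n_risk_snps=0,
        maf_low=0.3, maf_high=0.3, seed=7,
    )
    return gc.simulate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model():
    """A small trained separable model for screening unit tests."""
    rng = np.random.default_rng(5)
    layout = gc.layout_end_to_end(100, 10)
    # class 1 samples are mostly minor homozygote, class 0 mostly major
    codes0 = rng.choice([0, 1], size=(80, 100), p=[0.9, 0.1])
    codes1 = rng.choice([2, 1], size=(80, 100), p=[0.9, 0.1])
    images = [gc.encode_cc(c, layout, f"a{i}", 0) for i, c in enumerate(codes0)]
    images += [gc.encode_cc(c, layout, f"b{i}", 1) for i, c in enumerate(codes1)]
    x, y = gc.stack_images(images)
    cfg = gc.ModelConfig(input_side=10, input_channels=3, conv_filters=(4, 8, 8),
                         batch_size=32, max_epochs=8, seed=0)
    model = gc.build_model(cfg, gc.HyperParams(learning_rate=0.05))
    idx = np.random.default_rng(0).permutation(len(x))
    res = gc.train(model, x[idx[:120]], y[idx[:120]], x[idx[120:]], y[idx[120:]])
    return res.model, x, y, layout
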