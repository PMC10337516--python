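import numpy as np
import pytest

from ehrgan.data import FeatureSchema, ProcessedDataset
from ehrgan.graph import build_patient_graph
from ehrgan.synthetic import generate_gaussian_mixture


@pytest.fixture(scope="session")
def small_schema():
    return FeatureSchema(
        columns=[
            ("age", "numerical", None),
            ("sex", "categorical", ["M", "F"]),
            ("stage", "categorical", ["I", "II", "III"]),
        ],
        label_column="outcome",
    )


@pytest.fixture(scope="session")
def mixture_ds():
    """Unit-scaled 2-class Gaussian mixture wrapped as a ProcessedDataset."""
    X, y = generate_gaussian_mixture(300, 5, separation=4, seed=11)
    lo, hi = X.min(axis=0), X.max(axis=0)
    Xs = (X - lo) / (hi - lo)
    return ProcessedDataset(X=Xs, y=y, mask=np.ones(len(y), dtype=bool), M=2)


@pytest.fixture(scope="session")
def mixture_graph(mixture_ds):
    return build_patient_graph(mixture_ds.X, k=5)


@pytest.fixture(scope="session")
def tiny_gan_model(mixture_ds):
    """A small trained model shared by inference-surface tests."""
    from ehrgan.data import mask_labels
    from ehrgan.gan import GanConfig, train

    ds = mask_labels(mixture_ds, 0.2, seed=3)
    cfg = GanConfig(z_dim=16, gen_layers=(32,), disc_layers=(32,),
                    batch=64, max_epochs=3, seed=5)
    return train(ds.X, ds.y, ds.mask, cfg, feature_dim=ds.d)
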