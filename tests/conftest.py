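import numpy as np
import pytest

from popdann.genealogy import Genealogy
from popdann.scenarios import DatasetBundle


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def caterpillar3():
    """Leaves a=0, b=1 coalesce at t1=1; with c=2 at t2=3."""
    return Genealogy(
        n=3,
        node_times=np.array([0.0, 0.0, 0.0, 1.0, 3.0]),
        parent=np.array([3, 3, 4, 4, -1]),
    )


def synthetic_genealogy_bundle(
    n_examples=256,
    m=8,
    task="sweep_classification",
    seed=0,
    separation=2.0,
    target_shift=0.0,
    constant_label=None,
):
    """A synthetic encoded-genealogy bundle with a learnable class/label signal.

    The label signal is written redundantly into channels 0 and 1; the
    domain shift corrupts channel 0 of target examples only, so a
    domain-invariant feature extractor can recover the label from channel 1
    while a standard model trained on both is misled. Avoids coalescent
    simulation entirely, for fast training-loop tests.
    """
    rng = np.random.default_rng(seed)

    def make(n, shift, balanced=True):
        X = rng.normal(1.0, 0.5, size=(n, m, m, 3)).astype(np.float32)
        if task == "sweep_classification":
            y = (np.arange(n) % 2).astype(np.float32) if balanced else np.ones(n, np.float32)
            sig = separation * y[:, None, None]
        else:
            if constant_label is not None:
                y = np.full(n, constant_label, dtype=np.float32)
            else:
                y = rng.uniform(-3.0, -2.0, size=n).astype(np.float32)
            sig = separation * (y[:, None, None] + 2.5)
        # per-example random offsets: a mean shift (bias) plus extra variance
        # (ranking corruption), confined to channel 0
        offsets = shift * (1.0 + rng.normal(0.0, 0.5, size=(n, 1, 1))) if shift else 0.0
        X[:, :, :, 0] += (sig + offsets) * (m + 1)  # undo the 1/n input scaling
        X[:, :, :, 1] += sig
        return X * np.tri(m, dtype=np.float32)[None, :, :, None], y

    Xs, ys = make(n_examples, 0.0)
    Xt, yt = make(n_examples, target_shift)
    n_tr = int(0.8 * n_examples)
    n_va = int(0.1 * n_examples)
    return DatasetBundle(
        task=task,
        source_train=(Xs[:n_tr], ys[:n_tr]),
        source_val=(Xs[n_tr : n_tr + n_va], ys[n_tr : n_tr + n_va]),
        source_test=(Xs[n_tr + n_va :], ys[n_tr + n_va :]),
        target_train=Xt[:n_tr],
        target_val=Xt[n_tr : n_tr + n_va],
        target_test=(Xt[n_tr + n_va :], yt[n_tr + n_va :]),
        manifest={"synthetic": True},
    )


@pytest.fixture
def small_bundle():
    return synthetic_genealogy_bundle()
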