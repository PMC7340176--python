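import numpy as np
import pytest

from padpulse import abi, cohort, dataset_io, nn
from padpulse.arterial_tree import (
    ArterialTree,
    SegmentGeometry,
    load_default_tree,
)

MASTER_SEED = 1


@pytest.fixture(scope="session")
def default_tree() -> ArterialTree:
    return load_default_tree()


def make_toy_tree(n_harmless_loads: bool = True) -> ArterialTree:
    """7-segment asymmetric binary tree with one single-child chain."""
    g = SegmentGeometry
    segments = {
        1: g(4.0, 1.0, 0.10, 4e6),
        2: g(6.0, 0.6, 0.07, 4e6),
        3: g(8.0, 0.5, 0.06, 6e6),
        4: g(10.0, 0.35, 0.05, 8e6),
        5: g(12.0, 0.30, 0.05, 8e6),
        6: g(9.0, 0.28, 0.04, 8e6),
        7: g(7.0, 0.25, 0.04, 1.2e7),
    }
    parent = {1: None, 2: 1, 3: 1, 4: 2, 5: 2, 6: 3, 7: 6}
    terminal_load = {4: 9.0e4, 5: 1.4e5, 7: 1.1e5}
    return ArterialTree(
        segments=segments,
        parent=parent,
        names={i: f"seg{i}" for i in segments},
        terminal_load=terminal_load,
        site_map={"root": (1, "inlet"), "tip": (7, "outlet")},
    )


@pytest.fixture()
def toy_tree() -> ArterialTree:
    return make_toy_tree()


def planted_feature_data(n, rng, window=(50, 80), channel=0):
    """Inputs carry information only in one window of one channel: a
    Gaussian bump at samples 50-80 of the brachial row whose amplitude is
    the label; everything else is silence."""
    X = np.zeros((n, 2, 256))
    y = rng.uniform(0.1, 0.8, n)
    centre = (window[0] + window[1]) / 2
    for i in range(n):
        X[i, channel] = y[i] * np.exp(-0.5 * ((np.arange(256) - centre) / 6.0) ** 2)
    return X, y


@pytest.fixture(scope="session")
def planted_model():
    """Severity regressor trained on the planted-feature task.

    Batch norm is disabled here: its constant per-channel offsets add a
    spatially uniform saliency floor that reflects the normalisation, not
    the model's attribution, and this experiment measures attribution.
    """
    rng = np.random.default_rng(7)
    X, y = planted_feature_data(400, rng)
    Xv, yv = planted_feature_data(80, rng)
    model = nn.build_model(nn.NetworkConfig(batch_norm=False), seed=0)
    nn.train(
        model, (X, y), (Xv, yv),
        nn.TrainingConfig(epochs=60, learning_rate=1e-3, seed=0, patience=30),
    )
    return model


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """The full desk-scale study, run once and shared across tests.

    Simulates the mini cohort (train/validation/test), trains the severity
    regressor, computes DL and calibrated-ABI predictions over the test
    set, and returns every artifact needed by the evaluation and
    interpretability tests.
    """
    out = tmp_path_factory.mktemp("mini")
    tree = load_default_tree()
    manifests = cohort.mini_manifests(seed=MASTER_SEED)
    paths = {}
    for role, man in manifests.items():
        path = out / f"{role}.h5"
        recs = (rec for _s, rec in cohort.generate_dataset(man, tree))
        dataset_io.write_dataset(recs, path, manifest_hash=man.content_hash(), seed=man.seed)
        paths[role] = path

    datasets = {role: dataset_io.read_dataset(p) for role, p in paths.items()}
    x_train, y_train = nn.dataset_to_arrays(datasets["train"])
    x_val, y_val = nn.dataset_to_arrays(datasets["validation"])
    model = nn.build_model(seed=MASTER_SEED)
    nn.train(
        model,
        (x_train, y_train),
        (x_val, y_val),
        nn.TrainingConfig(epochs=100, seed=MASTER_SEED),
    )

    x_test, y_test = nn.dataset_to_arrays(datasets["test"])
    dl_pred = model.predict(x_test)
    calibration = abi.calibrate(tree)
    abis = np.array(
        [
            abi.compute_abi(b, a)
            for b, a in zip(datasets["test"].brachial_bp(), datasets["test"].ankle_bp())
        ]
    )
    abi_pred = calibration.predict(abis)

    index: dict[str, list[int]] = {}
    for i, pid in enumerate(datasets["test"].patient_ids):
        index.setdefault(pid, []).append(i)

    return dict(
        tree=tree,
        manifests=manifests,
        datasets=datasets,
        model=model,
        calibration=calibration,
        x_test=x_test,
        y_test=y_test,
        dl_pred=dl_pred,
        abi_pred=abi_pred,
        abis=abis,
        sample_index=index,
        seed=MASTER_SEED,
    )
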