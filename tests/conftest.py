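import numpy as np
import pytest

import segdigit as sd


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 4-digit scene specification."""
    return sd.default_scene(n_digits=4, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def clean_frame(clean_scene):
    return sd.render_frame(clean_scene, frame_id="clean")


@pytest.fixture(scope="session")
def recovery_protocol():
    """The standard end-to-end recovery experiment: 10 training snapshots,
    200-frame test stream (4 digits per frame, mild noise and scale jitter),
    x10 scale-jitter augmentation, SGDM-trained compact CNN, per-class
    anchors derived from the training annotations."""
    tmpl = sd.default_scene(n_digits=4, noise_sd=5.0, scale_jitter=(0.95, 1.05))
    train, test = sd.make_dataset(10, 200, tmpl, seed=42)
    model = sd.train_classifier(
        train,
        aug=sd.AugmentationConfig(replication_factor=10, scale_range=(0.9, 1.0)),
        tc=sd.TrainConfig(seed=42),
    )
    cfg = sd.default_pipeline_config(train, seed=42)
    return train, test, model, cfg


@pytest.fixture(scope="session")
def recovery_report(recovery_protocol):
    train, test, model, cfg = recovery_protocol
    return sd.evaluate_stream(test, cfg, model)
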