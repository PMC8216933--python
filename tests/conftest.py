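import hypothesis
import numpy as np
import pandas as pd
import pytest

from trapsift import PredictionManifest, asymmetric_group_preset, generate

hypothesis.settings.register_profile(
    "ci", hypothesis.settings(derandomize=True, max_examples=100)
)
hypothesis.settings.load_profile("ci")

SIX_MODELS = ["A1", "I1", "R1", "A2", "I2", "R2"]


def make_manifest(rows, model_ids=None):
    """Build a manifest from dict rows; fills site/truth/species when present."""
    model_ids = model_ids or SIX_MODELS
    df = pd.DataFrame(rows)
    return PredictionManifest(df, model_ids)


def six_prob_row(image_id, event_id, probs, truth=None, species=None):
    row = {"image_id": image_id, "event_id": event_id}
    if truth is not None:
        row["truth"] = truth
    if species is not None:
        row["species"] = species
    row.update(dict(zip(SIX_MODELS, probs)))
    return row


@pytest.fixture
def preset_manifest():
    """A moderate synthetic manifest from the default asymmetric preset."""
    return generate(asymmetric_group_preset(n_events=400, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
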