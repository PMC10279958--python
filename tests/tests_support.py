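"""Shared helpers for the test suite."""

import json
from importlib import resources

import numpy as np


def stored_hit_params() -> dict:
    """The stored reference hit parameter set (timecourse1)."""
    blob = resources.files("spnsim").joinpath("data/timecourse1_params.json")
    return json.loads(blob.read_text())


def stored_hit_vector(table) -> np.ndarray:
    ref = stored_hit_params()["sampled_parameters"]
    return table.vector_from_sampled(np.array([ref[n] for n in table.sampled_names]))
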