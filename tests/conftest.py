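import numpy as np
import pytest

from actinovelty.preprocessing import SynchronizedRecording
from actinovelty.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_motif_dictionary,
    tile_motif,
)


@pytest.fixture(scope="session")
def control_dict():
    return generate_motif_dictionary(4, seed=101)


@pytest.fixture(scope="session")
def divergent_dict():
    return generate_motif_dictionary(4, seed=202)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort: 2 per group, 2 minutes each."""
    return CohortSpec(n_per_group=2, duration_s=120.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, control_dict, divergent_dict):
    return generate_cohort(tiny_spec, control_dict, divergent_dict)


def motif_recording(dictionary, motif_index, n_samples, sd=0.5, pid="p"):
    """A synchronized recording made of one motif tiled without taper."""
    sig = tile_motif(
        dictionary.motifs[motif_index],
        dictionary.period_samples,
        n_samples,
        sd=sd,
        ramp=0,
    )
    return SynchronizedRecording(pid, 10.0, sig)


def brute_force_forward(params, x):
    """Independent step-by-step evaluation of the five gate equations.

    Deliberately naive: plain loops over time and layers, scalar-friendly
    numpy, no shared code with the package's batched implementation.
    """
    seq = [np.asarray(row, dtype=float) for row in x]
    for layer in params.layers:
        H = layer.hidden_size
        h = np.zeros(H)
        c = np.zeros(H)
        outputs = []
        for xt in seq:
            f = 1.0 / (1.0 + np.exp(-(layer.Wf.T @ xt + layer.Uf.T @ h + layer.bf)))
            i = 1.0 / (1.0 + np.exp(-(layer.Wi.T @ xt + layer.Ui.T @ h + layer.bi)))
            o = 1.0 / (1.0 + np.exp(-(layer.Wo.T @ xt + layer.Uo.T @ h + layer.bo)))
            c = f * c + i * np.tanh(layer.Wc.T @ xt + layer.Uc.T @ h + layer.bc)
            h = o * np.tanh(c)
            outputs.append(h)
        seq = outputs
    out = params.Wd.T @ seq[-1] + params.bd
    return out.reshape(20, 4)
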