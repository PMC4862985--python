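import numpy as np
import pytest

from cvrkit.mapping import QcSpec, compute_cvr_map
from cvrkit.protocol import HypercapniaProtocol, build_protocol_waveform
from cvrkit.synth import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_protocol():
    return HypercapniaProtocol()


@pytest.fixture(scope="session")
def reg255(default_protocol):
    """Default-protocol regressor: 255 volumes at TR 2 s."""
    return build_protocol_waveform(default_protocol, 2.0, 255)


@pytest.fixture(scope="session")
def short_protocol():
    """A compressed two-block schedule fitting 60 volumes at TR 2 s."""
    return HypercapniaProtocol(
        lead_in_s=20.0, block_durations_s=(30.0, 40.0), inter_block_s=20.0, tail_s=10.0
    )


@pytest.fixture(scope="session")
def reg60(short_protocol):
    return build_protocol_waveform(short_protocol, 2.0, 60)


@pytest.fixture(scope="session")
def noiseless_phantom(reg255):
    """Healthy-preset noiseless phantom with its regressor and truth field."""
    spec = PhantomSpec()
    bold, masks, truth = generate_phantom(spec, reg255)
    return spec, bold, masks, truth


@pytest.fixture(scope="session")
def noiseless_map(noiseless_phantom, reg255):
    spec, bold, masks, truth = noiseless_phantom
    cvr = compute_cvr_map(
        bold, reg255, qc=QcSpec(), analysis_mask=masks.head,
        baseline_mmHg=spec.baseline_mmHg,
    )
    return cvr, masks, truth


def elevated_runs(values, baseline, step):
    """Start/length (in samples) of each contiguous above-baseline plateau."""
    hot = np.asarray(values) > baseline + step / 2.0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts, ends - starts))
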