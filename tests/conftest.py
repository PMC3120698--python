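import numpy as np
import pytest

from fsalign.preprocess import PreprocessConfig
from fsalign.synth import example_25plex_spec, synth_pair, synth_trace
from fsalign.trace_io import TraceRecord, write_trace


@pytest.fixture
def plex_spec():
    """The bundled 25-peak layout, fixed seed."""
    return example_25plex_spec(seed=7)


@pytest.fixture
def reference_record(plex_spec):
    return synth_trace(plex_spec)


@pytest.fixture
def warped_pair():
    """Reference/target pair with three time-warp distortions and a
    leading voltage-spike artifact on the target."""
    spec = example_25plex_spec(
        seed=11,
        warp=[(400, "duplicate"), (600, "drop"), (900, "duplicate")],
        artifact=(10, 2000.0, 1.5),
    )
    return synth_pair(spec)


@pytest.fixture
def pair_files(tmp_path, warped_pair):
    ref, tgt, _ = warped_pair
    ref_path = tmp_path / "reference.fsa"
    tgt_path = tmp_path / "target.fsa"
    write_trace(ref, ref_path)
    write_trace(tgt, tgt_path)
    return ref_path, tgt_path


@pytest.fixture
def default_config():
    return PreprocessConfig()


def make_record(channels, **kwargs) -> TraceRecord:
    kwargs.setdefault("model", "3100")
    return TraceRecord(channels=[np.asarray(c) for c in channels], **kwargs)


@pytest.fixture
def make_trace():
    return make_record
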