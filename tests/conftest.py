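import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_melody_csv(path, rows):
    lines = ["onset_s,duration_s,pitch"]
    lines += [f"{o},{d},{p}" for o, d, p in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
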