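"""Shared fixtures: tiny constructed references and editing targets."""

from __future__ import annotations

import pytest


def make_reference(proto: str, pam: str, offset: int, total_len: int = 80, seed: int = 7) -> str:
    """Embed protospacer+PAM at a fixed offset inside a random ACGT string."""
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    flank = "".join(bases[i] for i in rng.integers(0, 4, size=total_len))
    insert = proto + pam
    return flank[:offset] + insert + flank[offset + len(insert):]


@pytest.fixture
def toy_target():
    """An 83-nt reference with a plus-strand protospacer at offset 30."""
    proto = "GATTACAGATTACAGATTAC"
    pam = "TGG"
    ref = make_reference(proto, pam, offset=30, total_len=80)
    return {"reference": ref, "protospacer": proto, "pam": pam, "start": 30}
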