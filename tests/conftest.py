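from __future__ import annotations

import numpy as np
import pytest

from tsmr.instruments import HarmonizedInstrument


def make_instruments(bx, by, se_out, se_exp=None, pvals=None) -> list[HarmonizedInstrument]:
    """Build a harmonized instrument list from plain arrays."""
    J = len(bx)
    se_exp = se_exp if se_exp is not None else [0.01] * J
    return [
        HarmonizedInstrument(
            variant_id=f"s{j + 1}",
            beta_exp=float(bx[j]),
            se_exp=float(se_exp[j]),
            beta_out=float(by[j]),
            se_out=float(se_out[j]),
            pval_exp=float(pvals[j]) if pvals is not None else 1e-9,
            n_exp=20000,
            n_out=20000,
        )
        for j in range(J)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
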