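import numpy as np
import pytest

from invrec import MarkerPanel, OriginVector


def make_panel(positions, chrom_length=None, chrom="chrX", masked=None):
    """A/T diagnostic panel at the given positions (test helper)."""
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    return MarkerPanel(
        chrom=chrom,
        chrom_length=int(chrom_length or (positions.max() + 1000 if n else 1000)),
        positions=positions,
        allele_p1=np.full(n, b"A"),
        allele_p2=np.full(n, b"T"),
        masked=masked,
    )


def make_vector(calls, offspring_id="off1"):
    return OriginVector(offspring_id, np.asarray(calls, dtype=np.int8))


@pytest.fixture
def small_panel():
    return make_panel([100, 200, 300, 400, 500, 600, 700, 800])
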