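import numpy as np
import pytest

# The ten published telomere-enriched lncRNA loci: location string (as
# printed, en-dash), strand label, span length in bases, log2 ratio.
PUBLISHED_LOCI = [
    ("chr16:4871450–4874336", "Reverse", 2887, 3.084),
    ("chr2:156213799–156216885", "Reverse", 3087, 2.477),
    ("chr18:13114368–13118513", "Forward", 4146, 2.430),
    ("chrX:90997596–91009570", "N.D.", 11975, 2.283),
    ("chrX:91000652–91005855", "Reverse", 5204, 2.145),
    ("chrX:11684505–11685304", "Forward", 800, 2.145),
    ("chrX:18734107–18744367", "Reverse", 10261, 2.101),
    ("chr6:31233513–31241062", "N.D.", 7550, 2.020),
    ("chr2:153325671–153352170", "N.D.", 26500, 1.463),
    ("chr6:83368262–83407280", "Reverse", 39019, 1.369),
]


def random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Uniform-random DNA sequences (test-local helper)."""
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
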