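import numpy as np
import pytest

from fawstrain.seqdata import DEFAULT_SEGMENTS, MarkerSegmentDef
from fawstrain.simulate import SimulationConfig


@pytest.fixture(scope="session")
def toy_segment() -> MarkerSegmentDef:
    """A short synthetic exon+intron segment with a known diagnostic column."""
    return MarkerSegmentDef(
        marker="TOY",
        segment_name="toy60",
        segment_length_nominal=60,
        diagnostic_site=10,
        c_allele="C",
        r_allele="T",
        exon_intron_boundaries=((1, 20, "exon"), (21, 60, "intron")),
    )


def small_config(seed: int = 0, n: int = 15, **overrides) -> SimulationConfig:
    """Default-parameter cohort scaled down to n specimens per collection cell."""
    base = SimulationConfig(seed=seed)
    cells = {k: n for k in base.n_per_collection}
    return base.replace(n_per_collection=cells, **overrides)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def segments():
    return DEFAULT_SEGMENTS


def random_seqs(rng, n: int, L: int, p=(0.25, 0.25, 0.25, 0.25)) -> list[str]:
    return ["".join(rng.choice(list("ACGT"), size=L, p=list(p))) for _ in range(n)]


def related_seqs(rng, n: int, L: int, div: float = 0.08) -> list[str]:
    """n sequences mutated independently from one random ancestor.

    Pairwise divergence ~2*div, safely inside the TN93 validity range.
    """
    base = rng.choice(list("ACGT"), size=L)
    out = []
    for _ in range(n):
        s = base.copy()
        for i in np.flatnonzero(rng.random(L) < div):
            s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
        out.append("".join(s))
    return out
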