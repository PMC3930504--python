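import numpy as np
import pytest

from sweepscape import HaplotypePanel


@pytest.fixture
def worked_panel() -> HaplotypePanel:
    """The 4-haplotype worked example {000, 100, 110, 111}.

    Derived counts per site are 3, 2, 1; S = 3; by hand: pi = 10/6,
    theta_W = 3/a_3, theta_H = 2(9+4+1)/12.
    """
    alleles = np.array(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 1],
        ]
    )
    return HaplotypePanel(
        alleles=alleles,
        positions=[100, 200, 300],
        pop_labels=["p"] * 4,
        polarized=True,
        region_length=1000,
    )


def random_panel(rng, n=6, s=10, region_length=10_000, pops=("A",)) -> HaplotypePanel:
    """Random polymorphic panel for property tests."""
    while True:
        alleles = rng.integers(0, 2, size=(n, s), dtype=np.int8)
        counts = alleles.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        if keep.sum() >= 2:
            alleles = alleles[:, keep]
            break
    m = alleles.shape[1]
    positions = np.sort(rng.choice(np.arange(region_length), size=m, replace=False))
    labels = np.array([pops[i % len(pops)] for i in range(n)])
    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        pop_labels=labels,
        polarized=True,
        region_length=region_length,
    )
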