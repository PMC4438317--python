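"""Shared fixtures: small deterministic synthetic communities."""
from __future__ import annotations

import numpy as np
import pytest

from amdscope import binning, synthetic
from amdscope.synthetic import GenomeSpec


@pytest.fixture(scope="session")
def small_truth():
    """Three 30 kb genomes at distinct GC, 10 genes each."""
    specs = [
        GenomeSpec(f"G{i + 1}", 30_000, gc, 3, seed=100 + i)
        for i, gc in enumerate((0.40, 0.50, 0.60))
    ]
    return synthetic.generate_community(specs, [0.90, 0.06, 0.04], 10, seed=7)


@pytest.fixture(scope="session")
def binning_community():
    """Five 300 kb order-3 genomes spanning GC 0.38-0.67, tiled into
    ~45 contigs each of 5-7.5 kb: the standard genome-recovery fixture."""
    gcs = np.linspace(0.38, 0.67, 5)
    specs = [
        GenomeSpec(f"G{i + 1:02d}", 300_000, float(gc), 3, seed=7000 + i)
        for i, gc in enumerate(gcs)
    ]
    truth = synthetic.generate_community(
        specs, [0.91, 0.03, 0.03, 0.02, 0.01], 50, seed=71)
    contigs = synthetic.fragment_genomes(truth, (5000, 7500), seed=72)
    return truth, contigs


@pytest.fixture(scope="session")
def binning_profiles(binning_community):
    _, contigs = binning_community
    ids, profiles = binning.tnf_profiles(contigs, min_len=3000)
    origins = {c.id: c.origin for c in contigs}
    return ids, profiles, [origins[i] for i in ids]
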