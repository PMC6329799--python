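import numpy as np
import pandas as pd
import pytest

from splicescreen import (
    Arm,
    CountMatrix,
    SampleMeta,
    ShrnaLibrary,
    ShrnaRecord,
    Timepoint,
)


def make_guides(n, length=21, seed=7):
    rng = np.random.default_rng(seed)
    nt = np.array(list("ACGT"))
    guides = set()
    while len(guides) < n:
        guides.add("".join(nt[rng.integers(0, 4, length)]))
    return sorted(guides)


@pytest.fixture
def small_library():
    """3 genes x 2 hairpins + 3 scrambled controls."""
    guides = make_guides(9)
    records = []
    for gi, gene in enumerate(["GENE_A", "GENE_B", "GENE_C"]):
        for j in range(2):
            records.append(ShrnaRecord(f"{gene}_sh{j+1}", gene, guides[gi * 2 + j]))
    for k in range(3):
        records.append(ShrnaRecord(f"SCR{k+1}", "", guides[6 + k], is_control=True))
    return ShrnaLibrary(records)


def two_arm_samples():
    metas = []
    for arm in (Arm.AML, Arm.COUNTER):
        for rep in (1, 2):
            for tp in (Timepoint.INPUT, Timepoint.OUTPUT):
                metas.append(
                    SampleMeta(f"{arm.value}_rep{rep}_{tp.value.lower()}", arm, rep, tp)
                )
    return metas


@pytest.fixture
def small_counts(small_library):
    """Deterministic two-arm count matrix over the small library."""
    rng = np.random.default_rng(11)
    metas = two_arm_samples()
    counts = pd.DataFrame(
        rng.integers(50, 500, size=(len(small_library), len(metas))),
        index=small_library.hairpin_ids,
        columns=[m.sample_id for m in metas],
    )
    return CountMatrix(counts, metas, small_library)
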