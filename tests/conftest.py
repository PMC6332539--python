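import numpy as np
import pandas as pd
import pytest

from lncstrat.pipeline import RunConfig, analyze, demo_spec
from lncstrat.synthetic import make_annotation, simulate_cohort


@pytest.fixture(scope="session")
def demo_setup():
    """One fully analyzed planted-truth cohort shared across tests."""
    spec = demo_spec(seed=7)
    ann = make_annotation(spec)
    cohort = simulate_cohort(spec, ann)
    cfg = RunConfig(subtypes=tuple(s for s, _ in spec.subtype_labels), B=200, seed=7)
    bundle = analyze(cohort.counts, cohort.fpkm, cohort.beta, cohort.samples,
                     ann.probes, ann.genes, ann.gene_sets, ann.chrom_states, cfg)
    return {"spec": spec, "ann": ann, "cohort": cohort, "cfg": cfg, "bundle": bundle}


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_genes():
    """A 20-gene toy chromosome with mixed strands and overlapping windows."""
    from lncstrat.annotation import GeneModel

    r = np.random.default_rng(31)
    genes = []
    pos = 1000
    for i in range(20):
        pos += int(r.integers(500, 15000))
        length = int(r.integers(1500, 9000))
        strand = "+" if r.random() < 0.5 else "-"
        start, end = pos, pos + length - 1
        if length > 4000:
            mid = start + length // 3
            exons = ((start, mid), (mid + 300, end))
        else:
            exons = ((start, end),)
        genes.append(GeneModel(f"G{i:02d}", "chrT", strand, start, end, exons,
                               "protein_coding"))
        pos = end
    return genes
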