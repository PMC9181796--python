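import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from splitrootseq import CountMatrix, SimulationDesign, simulate_counts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_count_matrix(counts, groups, lengths=None, gene_ids=None):
    """Hand-built CountMatrix: counts is genes x samples, groups per sample."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    seen: dict[str, int] = {}
    names = []
    for g in groups:
        seen[g] = seen.get(g, 0) + 1
        names.append(f"{g}_{seen[g]}")
    samples = pd.DataFrame(
        {
            "sample": names,
            "group": groups,
            "tissue": ["shoot" if g.endswith("_Sh") else "root" for g in groups],
            "condition": [g.rsplit("_", 1)[0] for g in groups],
            "replicate": [int(n.rsplit("_", 1)[1]) for n in names],
        }
    )
    df = pd.DataFrame(counts, index=gene_ids, columns=names)
    df.index.name = "gene_id"
    if lengths is None:
        lengths = np.full(n_genes, 1000)
    return CountMatrix(
        counts=df,
        samples=samples,
        gene_lengths=pd.Series(np.asarray(lengths), index=gene_ids, name="length"),
    )


@pytest.fixture(scope="session")
def planted_run():
    """A moderate planted simulation shared by downstream-stage tests."""
    design = SimulationDesign(
        n_genes=4000,
        effect_log2fc=3.0,
        dispersion=0.1,
        base_mean_log_range=(2.0, 3.5),
        seed=7,
        shoot_fraction=0.3,
    )
    cm, truth = simulate_counts(design)
    return design, cm, truth
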