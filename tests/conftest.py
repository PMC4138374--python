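import numpy as np
import pytest

from ricemix.datamodel import CONDITIONS, ExpressionMatrix, SampleMeta


def make_samples(timepoints=(21,), n_replicates=3):
    return [
        SampleMeta(sample_id=f"{cond}_t{tp}_r{r}", density=cond[:2],
                   nitrogen=cond[2:], timepoint=tp, replicate=r)
        for tp in timepoints
        for cond in CONDITIONS
        for r in range(1, n_replicates + 1)
    ]


def make_matrix(gene_profiles, timepoints=(21,), n_replicates=3, noise_sd=0.0, seed=0):
    """ExpressionMatrix with per-gene latent 4-condition profiles plus noise.

    ``gene_profiles``: dict gene_id -> length-4 sequence in (LDSN, LDLN,
    HDSN, HDLN) order, replicated at every timepoint.
    """
    samples = make_samples(timepoints, n_replicates)
    rng = np.random.default_rng(seed)
    cond_idx = [CONDITIONS.index(s.condition) for s in samples]
    gene_ids = list(gene_profiles)
    latent = np.array([list(gene_profiles[g]) for g in gene_ids], dtype=float)
    values = latent[:, cond_idx]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ExpressionMatrix(gene_ids=gene_ids, samples=samples, values=values)


@pytest.fixture
def tiny_matrix():
    """Three genes with distinct condition responses, noise-free triplicates."""
    return make_matrix({
        "flat": (5.0, 5.0, 5.0, 5.0),
        "hd_up": (5.0, 5.0, 8.0, 8.0),
        "ln_down": (5.0, 3.0, 5.0, 3.0),
    })
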