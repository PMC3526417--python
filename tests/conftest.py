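import numpy as np
import pandas as pd
import pytest

from introcold.formats_io import ExpressionMatrix, SampleDescriptor, make_sample_id
from introcold.synthetic_data import SimulationConfig, generate_dataset

SMALL_PLANTED = {
    "common_induced": 20,
    "common_repressed": 10,
    "recurrent_specific_induced": 10,
    "recurrent_specific_repressed": 8,
    "il_specific_induced": 9,
    "il_specific_repressed": 3,
    "constitutive_up_il": 6,
    "constitutive_down_il": 4,
    "down_then_up": 4,
    "up_then_down_il": 4,
}


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_genes=300, planted_counts=dict(SMALL_PLANTED))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def timecourse_matrix(
    log2_condition_means: np.ndarray,
    genes=None,
    genotypes=("recurrent",),
    timepoints=(2, 6, 12, 24, 48),
    n_rep: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expand per-condition log2 means (genes x conditions, conditions =
    genotype-major [control, *timepoints]) into a replicated linear matrix."""
    rng = np.random.default_rng(seed)
    n_genes, n_cond = log2_condition_means.shape
    assert n_cond == len(genotypes) * (1 + len(timepoints))
    samples, cols = [], []
    c = 0
    for genotype in genotypes:
        for cond, t in [("control", 0)] + [("cold", t) for t in timepoints]:
            for rep in range(1, n_rep + 1):
                samples.append(
                    SampleDescriptor(make_sample_id(genotype, cond, t, rep),
                                     genotype, cond, t, rep)
                )
                cols.append(log2_condition_means[:, c] + rng.normal(0, noise_sd, n_genes))
            c += 1
    if genes is None:
        genes = [f"t{i}" for i in range(n_genes)]
    df = pd.DataFrame(
        2.0 ** np.column_stack(cols), index=genes,
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(df, tuple(samples), scale="linear")


def toy_matrix(values: np.ndarray, n_rep: int = 0, genes=None) -> ExpressionMatrix:
    """Wrap a genes x samples array in a minimal 3v3 single-contrast design:
    columns are recurrent cold-24h reps then recurrent control reps."""
    n_genes, n_samples = values.shape
    assert n_samples % 2 == 0
    half = n_samples // 2
    samples = []
    for rep in range(1, half + 1):
        samples.append(
            SampleDescriptor(make_sample_id("recurrent", "cold", 24, rep),
                             "recurrent", "cold", 24, rep)
        )
    for rep in range(1, half + 1):
        samples.append(
            SampleDescriptor(make_sample_id("recurrent", "control", 0, rep),
                             "recurrent", "control", 0, rep)
        )
    if genes is None:
        genes = [f"t{i}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, tuple(samples), scale="linear")
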