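import numpy as np
import pandas as pd
import pytest

from proteoheat import IntensityMatrix, SampleDesign, SimConfig, generate_dataset


def toy_matrix(values, protein_ids=None, sample_ids=None, scale="log2-normalized"):
    """Small IntensityMatrix from a 2-D list; None entries become missing."""
    arr = np.array([[np.nan if v is None else float(v) for v in row] for row in values])
    pids = protein_ids or [f"P{i}" for i in range(1, arr.shape[0] + 1)]
    sids = sample_ids or [f"s{j}" for j in range(1, arr.shape[1] + 1)]
    df = pd.DataFrame(arr, index=pids, columns=sids)
    return IntensityMatrix.from_values(df, scale_flag=scale)


def design_24(days=(0, 6), reps=3):
    """The reference 24-sample factorial design."""
    rows = []
    for geno, klass in (("T1", "tolerant"), ("T2", "tolerant"),
                        ("S1", "sensitive"), ("S2", "sensitive")):
        for day in days:
            for rep in range(1, reps + 1):
                rows.append((f"{geno}_d{day}_r{rep}", geno, klass, day, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "genotype", "tolerance_class",
                                     "day", "replicate"]).set_index("sample_id")
    return SampleDesign(df)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared by read-mostly tests."""
    cfg = SimConfig(seed=42, n_proteins=400, n_day_effect=20, n_class_effect=10,
                    n_interaction=5, n_on_off=6, n_switch_like=6)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def complete_dataset():
    """Missingness-free dataset: the matrix doubles as its imputed form."""
    cfg = SimConfig(seed=7, n_proteins=400, n_day_effect=20, n_class_effect=10,
                    n_interaction=5, n_on_off=0, n_switch_like=0, missing_target=0.0)
    matrix, design, registry = generate_dataset(cfg)
    complete = IntensityMatrix(matrix.values, matrix.mask, "imputed")
    return complete, design, registry
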