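import numpy as np
import pandas as pd
import pytest

from dgetag.de import DifferentialCall
from dgetag.simulate import assign_gene_action_profiles, simulate_transcriptome
from dgetag.tags import ExpressionTable

N_LIB = 1_000_000


@pytest.fixture(scope="session")
def small_transcriptome():
    return simulate_transcriptome(300, frac_no_catg=0.1, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_transcriptome):
    return assign_gene_action_profiles(small_transcriptome, seed=2)


def make_table(counts: dict[str, dict[str, int]], n: int = N_LIB) -> ExpressionTable:
    """ExpressionTable from {gene: {P: c, M: c, F1: c}} with equal library sizes."""
    df = pd.DataFrame(counts).T
    df.index.name = "gene_id"
    return ExpressionTable(df[["P", "M", "F1"]], {"P": n, "M": n, "F1": n})


def make_call(
    gene_id: str,
    contrast: str,
    tpm_x: float,
    tpm_y: float,
    significant: bool,
    n: int = N_LIB,
) -> DifferentialCall:
    """Hand-built contrast call; direction follows the TPM ratio when significant."""
    l2r = float(np.log2((tpm_y or 0.5) / (tpm_x or 0.5)))
    return DifferentialCall(
        gene_id=gene_id,
        contrast=contrast,
        x=int(tpm_x),
        y=int(tpm_y),
        n1=n,
        n2=n,
        tpm_x=tpm_x,
        tpm_y=tpm_y,
        log2_ratio=l2r,
        p_value=0.0001 if significant else 0.9,
        fdr=0.0001 if significant else 0.9,
        significant=significant,
        direction=("up" if l2r > 0 else "down") if significant else "none",
    )
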