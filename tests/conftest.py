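import numpy as np
import pandas as pd
import pytest

from mrkit import SimConfig, harmonize, simulate_two_sample, usable_frame
from mrkit.sumstats import InstrumentSet, SummaryRecord


@pytest.fixture
def two_row_frame():
    """The two-variant worked example used by the IVW/heterogeneity oracles."""
    return pd.DataFrame({
        "SNP": ["rs1", "rs2"],
        "BETA_EXP": [0.2, 0.1], "SE_EXP": [0.01, 0.01],
        "BETA_OUT": [0.1, 0.06], "SE_OUT": [0.05, 0.03],
    })


@pytest.fixture
def clean_sim_table():
    """A clean (no pleiotropy) simulated harmonized table, theta = 0.5."""
    exposure, outcome, truth = simulate_two_sample(
        SimConfig(seed=7, theta=0.5, n_snps=100, total_r2=0.05))
    return usable_frame(harmonize(exposure, outcome)), truth


def make_record(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
                p=None, n=100_000, scale="sd", **kw):
    if p is None:
        from scipy import stats
        p = float(2 * stats.norm.sf(abs(beta / se)))
    return SummaryRecord(variant_id=vid, effect_allele=ea, other_allele=oa,
                         eaf=eaf, beta=beta, se=se, pvalue=p, n_total=n,
                         trait_scale=scale, **kw)


def make_set(records, name="trait"):
    return InstrumentSet(trait_name=name, records=list(records))


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a small canonical-dialect summary-statistics TSV, return path."""

    def _write(rows, name="sumstats.tsv", columns=None):
        df = pd.DataFrame(rows)
        if columns is not None:
            df = df[columns]
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
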