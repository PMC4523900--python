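"""Shared fixtures: toy transcripts and a small simulated cohort."""

import numpy as np
import pandas as pd
import pytest

from mrin.coverage import attach_rpkm
from mrin.gene_models import GeneModel, Transcript
from mrin.ks_core import build_ks_matrix
from mrin.synthetic import SimulationConfig, simulate_cohort


def make_transcript(tx_id="TX1", gene_id="G1", chrom="chr1", strand="+",
                    exons=((0, 100),), cds=None):
    return Transcript(
        transcript_id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(exons),
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
    )


def make_gene(**kw):
    tx = make_transcript(**kw)
    return GeneModel(gene_id=tx.gene_id, representative=tx)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-sample x 120-gene cohort with the default degradation mixture."""
    cohort = simulate_cohort(SimulationConfig(n_samples=30, n_genes=120, seed=7))
    attach_rpkm(cohort.profiles)
    return cohort


@pytest.fixture(scope="session")
def small_ks(small_cohort):
    return build_ks_matrix(small_cohort.profiles, mode="per_base")


@pytest.fixture()
def toy_ks_frame():
    """Hand-sized KS matrix with a missing cell."""
    from mrin.ks_core import KSMatrix

    d = pd.DataFrame(
        {
            "s1": [0.1, 0.1, 0.2],
            "s2": [0.2, np.nan, 0.1],
            "s3": [0.6, 0.5, 0.3],
        },
        index=["g1", "g2", "g3"],
    )
    reasons = d.isna().map(lambda x: "low_expression" if x else "")
    return KSMatrix(d=d, reasons=reasons)
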