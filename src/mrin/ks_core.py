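"""Signed KS statistic of 3' coverage bias and the gene x sample KS/mKS matrices.

For each gene and sample the per-base coverage profile (indexed from the
transcript 3' end) is turned into a cumulative distribution
``f(x) = c(x) / h`` and compared with the uniform null ``x / L``.  The signed
statistic

    d = f(x*) - x*/L,   x* = argmax_x |f(x) - x/L|

is positive under 3' bias and negative under 5' bias.  Per gene the KS
statistics are median-centred across samples (mKS), removing gene-intrinsic
coverage bias; gene-level exclusion filters (presence, s.d., median) define
the retained gene set used for mRIN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import CoverageProfile

__all__ = [
    "NoCoverageError",
    "CumulativeProfile",
    "cumulative",
    "ks_statistic",
    "ks_from_counts",
    "KSMatrix",
    "MKSMatrix",
    "FilterReport",
    "build_ks_matrix",
    "median_center",
    "filter_genes",
    "compute_mks",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

#: missing-cell reasons recorded in the KS matrix provenance
REASON_LOW_EXPRESSION = "low_expression"
REASON_NO_COVERAGE = "no_coverage"


class NoCoverageError(ValueError):
    """Profile has zero total coverage; the caller records a missing value."""


@dataclass
class CumulativeProfile:
    """Cumulative coverage c(x), total h and distribution f(x) = c(x)/h."""

    c: np.ndarray
    h: float
    f: np.ndarray

    @property
    def L(self) -> int:
        return int(self.c.size)


def cumulative(profile: CoverageProfile) -> CumulativeProfile:
    """Transform a coverage profile into its cumulative distribution."""
    h = profile.h
    if h <= 0:
        raise NoCoverageError(
            f"gene {profile.gene_id} sample {profile.sample_id}: no coverage"
        )
    c = np.cumsum(profile.n)
    return CumulativeProfile(c=c, h=h, f=c / h)


def ks_statistic(cum: CumulativeProfile) -> float:
    """Signed maximal deviation of f(x) from the uniform null x/L.

    Ties in |deviation| are broken by the smallest x.  With x indexed from
    the 3' end, 3'-concentrated coverage gives d > 0.
    """
    L = cum.L
    g = cum.f - np.arange(1, L + 1) / L
    i = int(np.argmax(np.abs(g)))
    return float(g[i])


def ks_from_counts(n) -> float:
    """Convenience: signed KS statistic straight from a count vector."""
    prof = CoverageProfile(gene_id="", sample_id="", n=np.asarray(n, dtype=float))
    return ks_statistic(cumulative(prof))


# --------------------------------------------------------------------------
# Matrices


@dataclass
class KSMatrix:
    """Genes x samples matrix of signed KS statistics.

    ``d`` holds the statistics with NaN for missing cells; ``reasons`` is a
    same-shaped string frame recording why a cell is missing ("" when
    present).
    """

    d: pd.DataFrame
    reasons: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.d.index)

    @property
    def samples(self) -> list[str]:
        return list(self.d.columns)


@dataclass
class MKSMatrix:
    """Median-centred KS matrix plus the retained gene subset."""

    values: pd.DataFrame
    retained_genes: list[str]

    @property
    def retained(self) -> pd.DataFrame:
        return self.values.loc[self.retained_genes]


@dataclass
class FilterReport:
    """Per-gene record of the presence/s.d./median exclusion filters."""

    table: pd.DataFrame  # presence_frac, sd, median_d, retained, reason

    @property
    def retained_genes(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g",
                          index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "FilterReport":
        tab = pd.read_csv(path, sep="\t", index_col="gene_id", na_values="NA",
                          keep_default_na=False)
        tab["retained"] = tab["retained"].astype(bool)
        return cls(tab)


def build_ks_matrix(
    profiles: Mapping[str, Mapping[str, CoverageProfile]],
    mode: str = "per_base",
    min_rpkm: float = 2.0,
    min_mean_coverage: float = 2.0,
) -> KSMatrix:
    """Assemble the genes x samples KS matrix under the expression filters.

    Parameters
    ----------
    profiles
        Mapping sample_id -> (gene_id -> CoverageProfile); all samples must
        share the same gene universe.
    mode
        ``per_base``: a cell is evaluated when mean coverage h/L >=
        ``min_mean_coverage`` and RPKM >= ``min_rpkm``.
        ``exon_level``: evaluated when RPKM > ``min_rpkm`` (strict).
    """
    if mode not in ("per_base", "exon_level"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = list(profiles)
    if not samples:
        raise ValueError("no samples")
    universe = list(profiles[samples[0]])
    uni_set = set(universe)
    for s in samples[1:]:
        if set(profiles[s]) != uni_set:
            raise ValueError(f"sample {s!r} has a different gene universe")

    d = np.full((len(universe), len(samples)), np.nan)
    reasons = np.full((len(universe), len(samples)), "", dtype=object)
    for j, s in enumerate(samples):
        for i, g in enumerate(universe):
            p = profiles[s][g]
            if p.rpkm is None:
                raise ValueError(
                    f"gene {g} sample {s}: RPKM not set; call gene_rpkm/attach_rpkm first"
                )
            if mode == "per_base":
                ok = p.mean_coverage >= min_mean_coverage and p.rpkm >= min_rpkm
            else:
                ok = p.rpkm > min_rpkm
            if not ok:
                reasons[i, j] = REASON_LOW_EXPRESSION
                continue
            try:
                d[i, j] = ks_statistic(cumulative(p))
            except NoCoverageError:
                reasons[i, j] = REASON_NO_COVERAGE
    return KSMatrix(
        d=pd.DataFrame(d, index=universe, columns=samples),
        reasons=pd.DataFrame(reasons, index=universe, columns=samples),
    )


def median_center(ks: KSMatrix) -> pd.DataFrame:
    """Subtract each gene's across-sample median from its row.

    Missing cells stay missing; an all-missing gene row stays all-missing.
    """
    if ks.d.shape[1] < 2:
        raise ValueError("median centring needs at least 2 samples")
    return ks.d.sub(ks.d.median(axis=1, skipna=True), axis=0)


def filter_genes(ks: KSMatrix, sd_quantile: float = 0.05,
                 min_presence: float = 0.5) -> FilterReport:
    """Gene-level exclusions, applied in order:

    1. presence: evaluated in strictly more than ``min_presence`` of samples;
    2. s.d.: across-sample s.d. of d strictly above the ``sd_quantile``
       quantile of s.d.s among presence-passing genes (drops the least
       variable genes; skipped with a warning for < 3 samples);
    3. median: median d across samples >= 0 (removes 5'-biased genes,
       typically annotation errors).
    """
    d = ks.d
    n_samples = d.shape[1]
    presence = d.notna().mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    median_d = d.median(axis=1, skipna=True)

    pass_presence = presence > min_presence
    if n_samples < 3:
        warnings.warn("fewer than 3 samples: s.d. filter skipped", stacklevel=2)
        pass_sd = pd.Series(True, index=d.index)
    elif not pass_presence.any():
        pass_sd = pd.Series(True, index=d.index)
    else:
        cut = float(np.nanquantile(sd[pass_presence], sd_quantile))
        pass_sd = sd > cut
    pass_median = median_d >= 0

    reason = pd.Series("", index=d.index, dtype=object)
    reason[pass_presence & pass_sd & ~pass_median] = "negative_median"
    reason[pass_presence & ~pass_sd] = "low_sd"
    reason[~pass_presence] = "low_presence"
    retained = pass_presence & pass_sd & pass_median
    table = pd.DataFrame(
        {
            "presence_frac": presence,
            "sd": sd,
            "median_d": median_d,
            "retained": retained,
            "reason": reason,
        }
    )
    return FilterReport(table)


def compute_mks(ks: KSMatrix, sd_quantile: float = 0.05,
                min_presence: float = 0.5) -> tuple[MKSMatrix, FilterReport]:
    """Median-centre the KS matrix and apply the gene exclusion filters."""
    report = filter_genes(ks, sd_quantile=sd_quantile, min_presence=min_presence)
    values = median_center(ks)
    return MKSMatrix(values=values, retained_genes=report.retained_genes), report


# --------------------------------------------------------------------------
# TSV I/O (genes as rows, "NA" for missing)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", index_label="gene_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", na_values="NA",
                       keep_default_na=False)
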