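"""Gene-specific degradation scores (GIS) and transcript-feature analysis.

The gene integrity score of a gene is the Pearson correlation between its
mKS values across samples and the per-sample quality vector (mRIN by
default; an external vector such as RIN may be substituted).  Negative GIS
marks transcripts that degrade faster than average.  Transcript structural
and sequence covariates (region lengths, GC content, AU-rich-element and
PUM2-motif content of the 3'UTR) are related to GIS by binned correlations
and grouped ordinary-least-squares regression on Fisher-transformed scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gene_models import GeneModel, Transcript

__all__ = [
    "FeatureError",
    "TranscriptFeatures",
    "compute_gis",
    "fisher_transform",
    "count_motif",
    "extract_features",
    "features_table",
    "bin_correlate",
    "regress_gis",
    "ranked_gene_lists",
    "DEFAULT_GROUPS",
    "GISModel",
    "GISResults",
]


class FeatureError(ValueError):
    """Transcript unsuitable for feature extraction (with a reason)."""


# --------------------------------------------------------------------------
# GIS


def compute_gis(mks: pd.DataFrame, quality: pd.Series,
                min_samples: int = 10) -> pd.DataFrame:
    """Per-gene Pearson correlation of mKS with the sample quality vector.

    The correlation for a gene uses only samples where both its mKS and the
    quality value are non-missing; genes with fewer than ``min_samples``
    such samples, or zero variance in either vector, get a missing GIS with
    a reason.

    Returns a DataFrame indexed by gene with columns gis, gis_fisher,
    n_samples_used, reason.
    """
    q = quality.reindex(mks.columns).astype(float)
    gis = np.full(mks.shape[0], np.nan)
    n_used = np.zeros(mks.shape[0], dtype=int)
    reason = np.full(mks.shape[0], "", dtype=object)
    qv = q.to_numpy()
    mv = mks.to_numpy(dtype=float)
    for i in range(mv.shape[0]):
        row = mv[i]
        mask = np.isfinite(row) & np.isfinite(qv)
        n = int(mask.sum())
        n_used[i] = n
        if n < min_samples:
            reason[i] = "too_few_samples"
            continue
        x, y = row[mask], qv[mask]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            reason[i] = "zero_variance"
            continue
        gis[i] = np.corrcoef(x, y)[0, 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fisher = np.where(np.isfinite(gis),
                          np.arctanh(np.clip(gis, -1 + 1e-6, 1 - 1e-6)), np.nan)
    return pd.DataFrame(
        {"gis": gis, "gis_fisher": fisher, "n_samples_used": n_used,
         "reason": reason},
        index=mks.index,
    )


def fisher_transform(gis: float) -> float:
    """Fisher z-transform atanh(g) = ln((1+g)/(1-g))/2; |g| = 1 is clipped
    to +/-(1 - 1e-6) with a warning."""
    g = float(gis)
    if abs(g) >= 1.0:
        warnings.warn(f"|GIS| = {abs(g)} clipped for Fisher transform", stacklevel=2)
        g = math.copysign(1.0 - 1e-6, g)
    return float(np.arctanh(g))


# --------------------------------------------------------------------------
# Transcript features

_IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"), "T": frozenset("U"),
    "W": frozenset("AU"), "S": frozenset("CG"), "M": frozenset("AC"),
    "K": frozenset("GU"), "R": frozenset("AG"), "Y": frozenset("CU"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}

ARE_MOTIF = "AUUUA"
PUM2_MOTIF = "UGUAHAUA"


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def count_motif(seq: str, motif: str) -> int:
    """Count occurrences of an IUPAC motif, overlapping matches included.

    DNA input is transcribed (T -> U) before matching.
    """
    s = _to_rna(seq)
    pats = [_IUPAC[ch] for ch in motif.upper()]
    m = len(pats)
    count = 0
    for i in range(len(s) - m + 1):
        if all(s[i + j] in pats[j] for j in range(m)):
            count += 1
    return count


def _gc(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TranscriptFeatures:
    """Structural and sequence covariates of one protein-coding transcript."""

    gene_id: str
    len_tx: int
    len_5utr: int
    len_cds: int
    len_3utr: int
    n_exons: int
    gc_5utr: float
    gc_cds: float
    gc_3utr: float
    are_count: int
    pum2_count: int

    @property
    def are_density(self) -> float:
        """AUUUA occurrences per kilobase of 3'UTR."""
        return self.are_count / (self.len_3utr / 1000.0)

    @property
    def pum2_density(self) -> float:
        return self.pum2_count / (self.len_3utr / 1000.0)


def extract_features(tx: Transcript, sequence: str, n_exons: int | None = None
                     ) -> TranscriptFeatures:
    """Region lengths, GC content and 3'UTR motif content of a coding
    transcript.

    ``sequence`` is the spliced transcript sequence, 5'->3', DNA or RNA
    alphabet.  Raises :class:`FeatureError` for non-coding transcripts, CDS
    length not a multiple of 3, a missing UTR, or a sequence/annotation
    length mismatch.
    """
    seq = _to_rna(str(sequence))
    L = tx.spliced_length
    if len(seq) != L:
        raise FeatureError(
            f"{tx.transcript_id}: sequence length {len(seq)} != spliced length {L}"
        )
    if not tx.is_coding:
        raise FeatureError(f"{tx.transcript_id}: non-coding")
    (u5s, u5e), (cs, ce), (u3s, u3e) = tx.transcript_regions()
    len_5utr, len_cds, len_3utr = u5e - u5s, ce - cs, u3e - u3s
    if len_cds % 3 != 0:
        raise FeatureError(f"{tx.transcript_id}: CDS length {len_cds} not a multiple of 3")
    if len_5utr == 0 or len_3utr == 0:
        raise FeatureError(f"{tx.transcript_id}: missing UTR annotation")
    utr5, cds, utr3 = seq[u5s:u5e], seq[cs:ce], seq[u3s:u3e]
    return TranscriptFeatures(
        gene_id=tx.gene_id,
        len_tx=L,
        len_5utr=len_5utr,
        len_cds=len_cds,
        len_3utr=len_3utr,
        n_exons=tx.n_exons if n_exons is None else n_exons,
        gc_5utr=_gc(utr5),
        gc_cds=_gc(cds),
        gc_3utr=_gc(utr3),
        are_count=count_motif(utr3, ARE_MOTIF),
        pum2_count=count_motif(utr3, PUM2_MOTIF),
    )


FEATURE_COLUMNS = [
    "len_tx", "len_5utr", "len_cds", "len_3utr", "n_exons",
    "gc_5utr", "gc_cds", "gc_3utr",
    "are_count", "pum2_count", "are_density", "pum2_density",
]


def features_table(genes: Sequence[GeneModel], sequences: Mapping[str, str]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for every gene with an available sequence.

    ``sequences`` maps transcript_id -> spliced sequence.  Returns
    (features DataFrame indexed by gene, skipped DataFrame with reasons).
    """
    rows, skipped = [], []
    for g in genes:
        tx = g.representative
        try:  # plain dicts and pyfaidx.Fasta both index by name
            seq = sequences[tx.transcript_id]
        except KeyError:
            skipped.append((g.gene_id, "no_sequence"))
            continue
        try:
            f = extract_features(tx, str(seq))
        except FeatureError as exc:
            skipped.append((g.gene_id, str(exc)))
            continue
        rows.append({
            "gene_id": f.gene_id,
            **{c: getattr(f, c) for c in FEATURE_COLUMNS},
        })
    feats = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=FEATURE_COLUMNS)
    skip = pd.DataFrame(skipped, columns=["gene_id", "reason"])
    return feats, skip


# --------------------------------------------------------------------------
# Binned correlation and grouped regression

DEFAULT_GROUPS: dict[str, list[str]] = {
    "lengths": ["log_len_tx", "log_len_5utr", "log_len_cds", "log_len_3utr",
                "n_exons"],
    "base_composition": ["gc_5utr", "gc_cds", "gc_3utr"],
    "regulatory": ["are_density", "pum2_density"],
}


def bin_correlate(features: pd.DataFrame, gis: pd.Series, bin_size: int = 100,
                  order_by: str = "len_tx") -> pd.Series:
    """Correlation of bin-averaged features with bin-averaged GIS.

    Genes (joined on their ids) are sorted by ``order_by`` and cut into
    consecutive complete bins of ``bin_size``; a trailing partial bin is
    dropped.  Returns the Pearson correlation across bins for every feature
    column (NaN where a feature is constant across bins).
    """
    joined = features.join(gis.rename("gis"), how="inner").dropna(subset=["gis"])
    joined = joined.sort_values(order_by, kind="mergesort")
    n_bins = len(joined) // bin_size
    if n_bins < 3:
        raise ValueError(f"only {n_bins} complete bins of {bin_size} genes; need >= 3")
    trimmed = joined.iloc[: n_bins * bin_size]
    labels = np.repeat(np.arange(n_bins), bin_size)
    means = trimmed.groupby(labels).mean()
    out = {}
    g = means["gis"].to_numpy()
    for col in features.columns:
        x = means[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(g) == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(x, g)[0, 1])
    return pd.Series(out, name="bin_correlation")


def _design(features: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=features.index)
    for col in ("len_tx", "len_5utr", "len_cds", "len_3utr"):
        if col in features:
            X[f"log_{col}"] = np.log(features[col].astype(float) + 1.0)
    for col in ("n_exons", "gc_5utr", "gc_cds", "gc_3utr",
                "are_density", "pum2_density"):
        if col in features:
            X[col] = features[col].astype(float)
    return X


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    cols = list(X.columns)
    keep: list[str] = []
    for c in cols:
        trial = keep + [c]
        if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
            keep.append(c)
        else:
            warnings.warn(f"dropping collinear regressor {c!r}", stacklevel=3)
    return X[keep]


def regress_gis(features: pd.DataFrame, gis_fisher: pd.Series,
                groups: Mapping[str, Sequence[str]] | None = None) -> dict:
    """Grouped OLS of Fisher-transformed GIS on transcript features.

    Lengths enter as log(x + 1); each named group is fitted separately and
    then all groups together ("combined").  Returns, per model, R-squared,
    the overall F-test P value, the coefficients and the sample size.
    """
    groups = dict(groups) if groups is not None else dict(DEFAULT_GROUPS)
    X_all = _design(features)
    y = gis_fisher.rename("gis_fisher")
    data = X_all.join(y, how="inner").dropna()
    combined_cols = [c for cols in groups.values() for c in cols]
    results = {}
    for name, cols in {**groups, "combined": combined_cols}.items():
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"group {name!r}: unknown regressors {missing}")
        X = _drop_collinear(data[list(cols)])
        model = sm.OLS(data["gis_fisher"], sm.add_constant(X))
        fit = model.fit()
        results[name] = {
            "r_squared": float(fit.rsquared),
            "f_pvalue": float(fit.f_pvalue),
            "n": int(fit.nobs),
            "coefficients": {k: float(v) for k, v in fit.params.items()},
        }
    return results


def ranked_gene_lists(gis: pd.DataFrame, n: int = 1000) -> dict[str, list[str]]:
    """Top-N most unstable (lowest GIS) and most stable (highest GIS) genes,
    for export to external enrichment tools."""
    ordered = gis.dropna(subset=["gis"]).sort_values("gis", kind="mergesort")
    return {
        "most_unstable": list(ordered.index[:n]),
        "most_stable": list(ordered.index[-n:][::-1]),
    }


# --------------------------------------------------------------------------
# Model / Results facade


class GISModel:
    """Gene-specific integrity model: mKS matrix against a quality vector."""

    def __init__(self, mks: pd.DataFrame, quality: pd.Series,
                 min_samples: int = 10):
        self.mks = mks
        self.quality = quality
        self.min_samples = min_samples

    def fit(self) -> "GISResults":
        table = compute_gis(self.mks, self.quality, self.min_samples)
        return GISResults(self, table)


class GISResults:
    """Per-gene integrity scores with a summary view."""

    def __init__(self, model: GISModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        ok = self.table["gis"].dropna()
        lines = [
            "Gene integrity score (GIS) results",
            "==================================",
            f"genes scored:        {ok.size} / {self.table.shape[0]}",
            f"median GIS:          {ok.median():.4f}" if ok.size else "median GIS: NA",
            f"fraction GIS < 0:    {(ok < 0).mean():.3f}" if ok.size else "",
        ]
        return "\n".join(l for l in lines if l)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g",
                          index_label="gene_id")
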