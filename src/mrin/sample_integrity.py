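"""Per-sample mRIN, the null model of non-degraded samples, and significance.

The mRIN of a sample is the negative mean of its (median-centred) mKS values
over the retained genes; non-degraded samples have mRINs near zero while
degraded samples drift negative.  The null distribution N(mu, sigma^2) of
non-degraded samples is estimated either

* ``mad`` — mu = 0, sigma = 1.4826 x median(|mRIN|) over samples with
  positive mRIN (robust when few samples are degraded), or
* ``truncnorm`` — samples with mRIN above a cutoff alpha are assumed
  non-degraded and to follow a normal truncated below at alpha; (mu, sigma)
  are recovered from the truncated sample moments, and alpha is chosen by a
  grid search over [-0.05, 0.05] in steps of 0.0005 minimising a KS
  goodness-of-fit statistic D between the empirical CDF of the kept samples
  and the fitted truncated-normal CDF.

Each sample then gets z = (mRIN - mu) / sigma and a one-sided
P = Phi(z) (lower tail: small mRIN, small P).

The model/results pair (:class:`MRINModel`, :class:`MRINResults`) wraps this
pipeline in the usual fit/summary idiom.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .ks_core import KSMatrix, MKSMatrix, FilterReport, compute_mks

__all__ = [
    "NullModel",
    "compute_mrin",
    "fit_null_mad",
    "truncated_moments",
    "solve_moment_equations",
    "alpha_grid",
    "fit_null_truncnorm",
    "significance",
    "MRINModel",
    "MRINResults",
]

MAD_SCALE = 1.4826  # consistency constant for a normal distribution


@dataclass
class NullModel:
    """Fitted null distribution of non-degraded sample mRINs."""

    method: str  # "mad" or "truncnorm"
    alpha: float | None
    mu: float
    sigma: float
    D: float | None
    n_kept: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NullModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def compute_mrin(mks: MKSMatrix | pd.DataFrame,
                 retained_genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample mRIN = -(mean of non-missing mKS over retained genes).

    Returns a DataFrame indexed by sample with columns ``mrin`` and
    ``n_genes_used``.  A sample with zero evaluable genes gets a missing
    mRIN (excluded from null fitting downstream).
    """
    if isinstance(mks, MKSMatrix):
        values = mks.retained if retained_genes is None else mks.values
    else:
        values = mks
    if retained_genes is not None:
        values = values.loc[list(retained_genes)]
    if values.shape[0] == 0:
        raise ValueError("no retained genes")
    n_used = values.notna().sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mrin = -values.mean(axis=0, skipna=True)
    mrin[n_used == 0] = np.nan
    return pd.DataFrame({"mrin": mrin, "n_genes_used": n_used.astype(int)})


def fit_null_mad(mrins, scale: float = MAD_SCALE) -> NullModel:
    """Scaled-MAD null: mu = 0, sigma from positive mRINs only.

    The MAD is taken about the assumed null mean 0, i.e. sigma =
    scale x median(mRIN) over samples with mRIN > 0.
    """
    m = np.asarray(mrins, dtype=float)
    m = m[np.isfinite(m)]
    pos = m[m > 0]
    if pos.size == 0:
        raise ValueError(
            "no samples with positive mRIN; use the truncnorm null method"
        )
    sigma = scale * float(np.median(pos))
    return NullModel(method="mad", alpha=None, mu=0.0, sigma=sigma, D=None,
                     n_kept=int(pos.size))


# --------------------------------------------------------------------------
# Truncated-normal machinery


def _hazard(a: float) -> float:
    """lambda(a) = phi(a) / (1 - Phi(a)), computed stably."""
    return float(np.exp(norm.logpdf(a) - norm.logsf(a)))


def truncated_moments(mu: float, sigma: float, alpha: float) -> tuple[float, float]:
    """Mean and variance of N(mu, sigma^2) truncated below at alpha.

    With a = (alpha - mu)/sigma and lambda(a) = phi(a)/(1 - Phi(a)):
    mean = mu + sigma*lambda(a), variance = sigma^2 (1 + a*lambda - lambda^2).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = (alpha - mu) / sigma
    lam = _hazard(a)
    mean = mu + sigma * lam
    var = sigma**2 * (1.0 + a * lam - lam**2)
    return mean, var


def _moment_ratio(a: float) -> float:
    # variance / (mean - alpha)^2 of the standard truncated normal; depends
    # on a alone, which reduces the moment system to one dimension.
    lam = _hazard(a)
    return (1.0 + a * lam - lam**2) / (lam - a) ** 2


def solve_moment_equations(M0: float, S0sq: float, alpha: float,
                           bracket: tuple[float, float] = (-40.0, 40.0)
                           ) -> tuple[float, float] | None:
    """Invert the truncated-normal moments: find (mu, sigma) with truncated
    mean M0 and variance S0sq given truncation point alpha.

    Solved by a bracketed 1-D root search in a = (alpha - mu)/sigma, since
    S0sq / (M0 - alpha)^2 depends on a alone.  Returns ``None`` when the
    moments are infeasible or no root lies in the bracket.
    """
    if S0sq <= 0 or M0 <= alpha:
        return None
    target = S0sq / (M0 - alpha) ** 2
    lo, hi = bracket

    def f(a: float) -> float:
        return _moment_ratio(a) - target

    try:
        flo, fhi = f(lo), f(hi)
        if not np.isfinite(flo) or not np.isfinite(fhi) or flo * fhi > 0:
            return None
        a = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    except (ValueError, RuntimeError):
        return None
    lam = _hazard(a)
    sigma = (M0 - alpha) / (lam - a)
    if sigma <= 0:
        return None
    mu = alpha - a * sigma
    return float(mu), float(sigma)


def alpha_grid(alpha_min: float = -0.05, alpha_max: float = 0.05,
               step: float = 0.0005) -> np.ndarray:
    """Inclusive grid of candidate truncation thresholds."""
    n = int(round((alpha_max - alpha_min) / step)) + 1
    return np.linspace(alpha_min, alpha_max, n)


def _gof_D(kept: np.ndarray, mu: float, sigma: float, alpha: float) -> float:
    """KS distance between the empirical CDF of the kept mRINs and the
    fitted truncated-normal CDF (analytic)."""
    xs = np.sort(kept)
    n = xs.size
    a = (alpha - mu) / sigma
    tail = norm.sf(a)
    F = (norm.cdf((xs - mu) / sigma) - norm.cdf(a)) / tail
    i = np.arange(1, n + 1)
    return float(max(np.max(np.abs(F - i / n)), np.max(np.abs(F - (i - 1) / n))))


def fit_null_truncnorm(mrins, alpha_min: float = -0.05, alpha_max: float = 0.05,
                       step: float = 0.0005, min_kept: int = 5,
                       p_adequate: float = 0.1) -> NullModel:
    """Grid search over the truncation threshold alpha.

    For each alpha, samples with mRIN strictly above alpha are kept; their
    sample mean and variance feed :func:`solve_moment_equations`, and the
    candidate fit is scored by the KS goodness-of-fit D between the kept
    samples and the fitted truncated-normal CDF.

    Two safeguards make the search identifiable (conditional tail moments
    alone cannot pin down mu, and the raw smallest-D rule systematically
    favours heavy truncation because a two-parameter tail fit always matches
    a smaller subset better):

    * count consistency -- degraded samples lie below the cutoff by
      assumption, so the candidate's tail probability P(X > alpha) must be
      at least the observed kept fraction (minus twice its binomial
      standard error);
    * parsimony -- among candidates whose D is statistically adequate
      (one-sample KS p-value >= ``p_adequate``) the one keeping the most
      samples wins, i.e. the least truncation that still fits; only when no
      candidate fits adequately does the smallest D decide.

    Ties are broken by the smallest alpha.  Falls back to the scaled-MAD
    fit with a warning if no alpha is feasible.
    """
    from scipy.stats import kstwo

    m = np.asarray(mrins, dtype=float)
    m = m[np.isfinite(m)]
    if m.size < 20:
        warnings.warn(
            f"only {m.size} samples: truncated-normal null fit may be unstable",
            stacklevel=2,
        )
    candidates: list[tuple[NullModel, float]] = []
    for alpha in alpha_grid(alpha_min, alpha_max, step):
        kept = m[m > alpha]
        if kept.size < min_kept:
            continue
        M0 = float(kept.mean())
        S0sq = float(kept.var(ddof=1))
        sol = solve_moment_equations(M0, S0sq, alpha)
        if sol is None:
            continue
        mu, sigma = sol
        obs_frac = kept.size / m.size
        se = np.sqrt(obs_frac * (1.0 - obs_frac) / m.size)
        if norm.sf((alpha - mu) / sigma) < obs_frac - 2.0 * se:
            continue
        D = _gof_D(kept, mu, sigma, alpha)
        model = NullModel(method="truncnorm", alpha=float(alpha), mu=mu,
                          sigma=sigma, D=D, n_kept=int(kept.size))
        candidates.append((model, float(kstwo.sf(D, kept.size))))
    if not candidates:
        warnings.warn(
            "no feasible truncation threshold; falling back to scaled-MAD null",
            stacklevel=2,
        )
        return fit_null_mad(m)
    adequate = [c for c, p in candidates if p >= p_adequate]
    if adequate:
        # most samples kept, then smallest alpha (grid order already
        # ascending in alpha, and n_kept is non-increasing in alpha)
        return max(adequate, key=lambda c: c.n_kept)
    return min(candidates, key=lambda cp: (cp[0].D, cp[0].alpha))[0]


def significance(samples: pd.DataFrame, null: NullModel) -> pd.DataFrame:
    """Add z = (mrin - mu)/sigma and one-sided lower-tail P = Phi(z)."""
    out = samples.copy()
    out["z"] = (out["mrin"] - null.mu) / null.sigma
    out["p"] = norm.cdf(out["z"])
    return out


# --------------------------------------------------------------------------
# Model / Results facade


class MRINModel:
    """Per-sample mRNA-integrity model over an mKS matrix.

    Parameters
    ----------
    mks
        Median-centred KS values (genes x samples DataFrame or
        :class:`MKSMatrix`).
    retained_genes
        Genes to average over; defaults to the matrix's retained set (or all
        genes for a bare DataFrame).
    method
        Null-fitting method, ``truncnorm`` (default) or ``mad``.
    """

    def __init__(self, mks, retained_genes: Sequence[str] | None = None,
                 method: str = "truncnorm"):
        if method not in ("truncnorm", "mad"):
            raise ValueError(f"unknown null method {method!r}")
        if isinstance(mks, MKSMatrix):
            self.mks = mks.values
            self.retained_genes = (
                list(retained_genes) if retained_genes is not None
                else list(mks.retained_genes)
            )
        else:
            self.mks = mks
            self.retained_genes = (
                list(retained_genes) if retained_genes is not None
                else list(mks.index)
            )
        self.method = method
        self.filter_report: FilterReport | None = None

    @classmethod
    def from_ks_matrix(cls, ks: KSMatrix, method: str = "truncnorm",
                       sd_quantile: float = 0.05,
                       min_presence: float = 0.5) -> "MRINModel":
        """Build from a raw KS matrix, applying median-centring and the
        gene exclusion filters."""
        mks, report = compute_mks(ks, sd_quantile=sd_quantile,
                                  min_presence=min_presence)
        model = cls(mks, method=method)
        model.filter_report = report
        return model

    def fit(self, **null_kwargs) -> "MRINResults":
        table = compute_mrin(self.mks, self.retained_genes)
        usable = table["mrin"].dropna().to_numpy()
        if self.method == "mad":
            null = fit_null_mad(usable, **null_kwargs)
        else:
            null = fit_null_truncnorm(usable, **null_kwargs)
        table = significance(table, null)
        return MRINResults(self, table, null)


class MRINResults:
    """Fitted per-sample integrity results.

    Attributes
    ----------
    samples : pandas.DataFrame
        Indexed by sample_id with columns mrin, n_genes_used, z, p.
    null : NullModel
        The fitted null distribution.
    """

    def __init__(self, model: MRINModel, samples: pd.DataFrame, null: NullModel):
        self.model = model
        self.samples = samples
        self.null = null

    def degraded(self, p_cutoff: float = 0.05) -> list[str]:
        """Sample ids called degraded at the given one-sided P cutoff."""
        mask = self.samples["p"] < p_cutoff
        return list(self.samples.index[mask.fillna(False)])

    def summary(self, p_cutoffs: Sequence[float] = (0.05, 0.1, 0.25)) -> str:
        n = self.samples.shape[0]
        lines = [
            "mRIN sample-integrity results",
            "=============================",
            f"samples:            {n}",
            f"genes used (median): {int(self.samples['n_genes_used'].median())}",
            f"null method:        {self.null.method}",
        ]
        if self.null.alpha is not None:
            lines.append(f"alpha:              {self.null.alpha:.4f}")
        lines.append(f"mu:                 {self.null.mu:.6g}")
        lines.append(f"sigma:              {self.null.sigma:.6g}")
        if self.null.D is not None:
            lines.append(f"goodness-of-fit D:  {self.null.D:.4g}")
        lines.append(f"samples in null fit: {self.null.n_kept}")
        for cut in p_cutoffs:
            k = len(self.degraded(cut))
            lines.append(
                f"degraded at P<{cut:<5}: {k} ({100.0 * k / max(n, 1):.1f}%)"
            )
        return "\n".join(lines)

    def to_tsv(self, path, p_cutoffs: Sequence[float] = (0.05, 0.1, 0.25)) -> None:
        out = self.samples.copy()
        for cut in p_cutoffs:
            label = f"degraded_p{cut}".replace("0.", "")
            out[label] = (out["p"] < cut).fillna(False).astype(int)
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g",
                   index_label="sample_id")

    @staticmethod
    def read_samples_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA",
                           keep_default_na=False)
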