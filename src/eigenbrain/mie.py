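"""Welch's t-test score screening and most-important-eigenbrain selection.

For every key slice, the per-subject scores on the leading eigenbrains are
compared between classes with a two-sided Welch's t-test (unequal variances,
Welch-Satterthwaite degrees of freedom). The most important eigenbrain (MIE)
is the smallest-index eigenbrain significant on EVERY key slice; its score
on each key slice becomes one classification feature per subject.

A bundled worked-example table of per-slice score group statistics for a
98-vs-28 cohort (``data/reference_score_stats.csv``) allows the selection
rule to be exercised from summary statistics alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, SelectionError, SingleClassError
from .eigen import EigenbrainSet

__all__ = [
    "WTTResult",
    "FeatureMatrix",
    "welch_ttest",
    "welch_ttest_samples",
    "wtt_table",
    "wtt_from_summary",
    "select_mie",
    "select_mie_from_wtt",
    "build_features",
    "load_reference_score_stats",
    "REFERENCE_N_NC",
    "REFERENCE_N_AD",
]

REFERENCE_N_NC = 98
REFERENCE_N_AD = 28


@dataclass
class WTTResult:
    """Welch's-t screening of eigenbrain scores, slice x eigenbrain-rank.

    All matrices are (n_slices, n_ranks); ``ranks`` are 1-based eigenbrain
    ranks (rank r corresponds to 0-based eigenbrain index r - 1).
    """

    slice_ids: np.ndarray
    ranks: np.ndarray
    nc_mean: np.ndarray
    nc_sd: np.ndarray
    ad_mean: np.ndarray
    ad_sd: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    n_nc: int
    n_ad: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (slice, rank, group summaries, t, df, p)."""
        rows = []
        for i, sl in enumerate(self.slice_ids):
            for j, rk in enumerate(self.ranks):
                rows.append(
                    {
                        "slice": sl,
                        "rank": rk,
                        "nc_mean": self.nc_mean[i, j],
                        "nc_sd": self.nc_sd[i, j],
                        "ad_mean": self.ad_mean[i, j],
                        "ad_sd": self.ad_sd[i, j],
                        "t": self.t[i, j],
                        "df": self.df[i, j],
                        "p": self.p[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def passing_ranks(self, alpha: float = 0.05) -> np.ndarray:
        """1-based ranks whose p-value is below alpha on every slice."""
        ok = (self.p < alpha).all(axis=0)
        return self.ranks[ok]


@dataclass
class FeatureMatrix:
    """N x n_key_slices matrix of MIE scores, one column per key slice."""

    X: np.ndarray
    key_indices: tuple[int, ...]
    mie_index: int
    subject_ids: list[str]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def welch_ttest(m1, s1, n1, m2, s2, n2):
    """Two-sided Welch's t-test from group summary statistics.

    Returns (t, df, p) with t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) and
    Welch-Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise DataError("standard deviations must be nonnegative")
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise DataError("zero pooled standard error: t undefined")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_ttest_samples(a, b):
    """Welch's t-test from two raw sample vectors (sample SD, N-1 denominator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_ttest(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def wtt_from_summary(
    slice_ids, ranks, nc_mean, nc_sd, ad_mean, ad_sd, n_nc, n_ad
) -> WTTResult:
    """Build a WTTResult from (n_slices, n_ranks) summary-statistic arrays."""
    nc_mean = np.asarray(nc_mean, dtype=float)
    nc_sd = np.asarray(nc_sd, dtype=float)
    ad_mean = np.asarray(ad_mean, dtype=float)
    ad_sd = np.asarray(ad_sd, dtype=float)
    t = np.empty_like(nc_mean)
    df = np.empty_like(nc_mean)
    p = np.empty_like(nc_mean)
    for i in range(nc_mean.shape[0]):
        for j in range(nc_mean.shape[1]):
            t[i, j], df[i, j], p[i, j] = welch_ttest(
                nc_mean[i, j], nc_sd[i, j], n_nc, ad_mean[i, j], ad_sd[i, j], n_ad
            )
    return WTTResult(
        slice_ids=np.asarray(slice_ids),
        ranks=np.asarray(ranks, dtype=int),
        nc_mean=nc_mean,
        nc_sd=nc_sd,
        ad_mean=ad_mean,
        ad_sd=ad_sd,
        t=t,
        df=df,
        p=p,
        n_nc=n_nc,
        n_ad=n_ad,
    )


def wtt_table(
    eigen_sets: list[EigenbrainSet], labels, max_rank: int = 6
) -> WTTResult:
    """Welch-screen the first ``max_rank`` eigenbrains of every key slice."""
    if not eigen_sets:
        raise DataError("need at least one key slice")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("both classes required for the t-test")
    n_ranks = min(max_rank, min(es.n_eig for es in eigen_sets))
    if n_ranks == 0:
        raise DataError("an eigenbrain set is empty")
    shape = (len(eigen_sets), n_ranks)
    nc_mean = np.empty(shape)
    nc_sd = np.empty(shape)
    ad_mean = np.empty(shape)
    ad_sd = np.empty(shape)
    nc = labels == 0
    ad = labels == 1
    for i, es in enumerate(eigen_sets):
        for j in range(n_ranks):
            s_nc = es.scores[nc, j]
            s_ad = es.scores[ad, j]
            nc_mean[i, j] = s_nc.mean()
            nc_sd[i, j] = s_nc.std(ddof=1)
            ad_mean[i, j] = s_ad.mean()
            ad_sd[i, j] = s_ad.std(ddof=1)
    return wtt_from_summary(
        slice_ids=np.array([es.key_index for es in eigen_sets]),
        ranks=np.arange(1, n_ranks + 1),
        nc_mean=nc_mean,
        nc_sd=nc_sd,
        ad_mean=ad_mean,
        ad_sd=ad_sd,
        n_nc=int(nc.sum()),
        n_ad=int(ad.sum()),
    )


def select_mie_from_wtt(wtt: WTTResult, alpha: float = 0.05) -> int:
    """Smallest 0-based eigenbrain index significant on every slice."""
    passing = wtt.passing_ranks(alpha)
    if passing.size == 0:
        raise SelectionError(
            f"no eigenbrain index has p < {alpha} on every key slice", result=wtt
        )
    return int(passing.min()) - 1


def select_mie(
    eigen_sets: list[EigenbrainSet], labels, alpha: float = 0.05, max_rank: int = 6
) -> tuple[int, WTTResult]:
    """Welch-screen the leading eigenbrains and pick the MIE (0-based index)."""
    wtt = wtt_table(eigen_sets, labels, max_rank=max_rank)
    return select_mie_from_wtt(wtt, alpha=alpha), wtt


def build_features(eigen_sets: list[EigenbrainSet], mie_index: int) -> FeatureMatrix:
    """Assemble the N x n_key_slices matrix of MIE scores."""
    if not eigen_sets:
        raise DataError("need at least one key slice")
    for es in eigen_sets:
        if not 0 <= mie_index < es.n_eig:
            raise ConfigurationError(
                f"mie_index {mie_index} out of range for slice {es.key_index}"
            )
    X = np.column_stack([es.scores[:, mie_index] for es in eigen_sets])
    return FeatureMatrix(
        X=X,
        key_indices=tuple(int(es.key_index) for es in eigen_sets),
        mie_index=mie_index,
        subject_ids=list(eigen_sets[0].subject_ids),
    )


def load_reference_score_stats() -> tuple[WTTResult, pd.DataFrame]:
    """Load the bundled 98-vs-28 worked-example summary table.

    Returns the recomputed WTTResult plus the raw table (including the
    reference p-values rounded to two decimals, column ``printed_p``).
    """
    with resources.files("eigenbrain.data").joinpath(
        "reference_score_stats.csv"
    ).open() as fh:
        raw = pd.read_csv(fh)
    slices = np.sort(raw["slice"].unique())
    ranks = np.sort(raw["rank"].unique())
    wide = raw.set_index(["slice", "rank"]).sort_index()

    def grid(col):
        return np.array(
            [[wide.loc[(s, r), col] for r in ranks] for s in slices], dtype=float
        )

    wtt = wtt_from_summary(
        slice_ids=slices,
        ranks=ranks,
        nc_mean=grid("nc_mean"),
        nc_sd=grid("nc_sd"),
        ad_mean=grid("ad_mean"),
        ad_sd=grid("ad_sd"),
        n_nc=REFERENCE_N_NC,
        n_ad=REFERENCE_N_AD,
    )
    return wtt, raw
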