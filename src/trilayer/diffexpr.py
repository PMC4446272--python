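"""Two-group differential expression with a moderated t-statistic.

The contrast is always high-fat diet (HFD) minus low-fat diet (LFD) on
log2 expression values, one test per gene and per timepoint.  The
statistic is a shrinkage t: the per-gene pooled variance is blended with
a common prior variance, which stabilises the denominator when group
sizes are small (n = 10-12 per diet).

With ``prior_df = 0`` the statistic reduces exactly to the ordinary
equal-variance pooled two-sample t.  With ``prior_df -> inf`` every gene
is tested against the common variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ExpressionMatrix", "moderated_ttest", "bh_adjust"]

GROUPS = ("HFD", "LFD")


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with per-sample diet/timepoint labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``diet`` (``HFD`` or
        ``LFD``) and ``timepoint``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")
        bad = set(self.samples.loc[list(self.values.columns), "diet"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown diet labels: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def timepoints(self) -> list[str]:
        tps = self.samples.loc[list(self.values.columns), "timepoint"]
        return sorted(tps.unique())

    def subset(self, timepoint: str) -> "ExpressionMatrix":
        """Restrict to the samples of one timepoint."""
        keep = self.samples.index[self.samples["timepoint"] == timepoint]
        cols = [c for c in self.values.columns if c in set(keep)]
        if not cols:
            raise ValueError(f"no samples at timepoint {timepoint!r}")
        return ExpressionMatrix(self.values[cols], self.samples.loc[cols])

    def group_columns(self, diet: str) -> list[str]:
        labels = self.samples.loc[list(self.values.columns), "diet"]
        return [c for c in self.values.columns if labels[c] == diet]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-d sequence")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_ttest(
    expr: ExpressionMatrix,
    prior_df: float = 4.0,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test, HFD vs LFD, one row per gene.

    The pooled per-gene variance ``s_g^2`` (d_g = nA + nB - 2 df) is
    shrunk toward a prior ``s0^2``::

        s~^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

    with ``d0 = prior_df`` and ``s0^2 = prior_var`` (default: the mean
    pooled variance across genes).  Two-sided p values come from a
    t-distribution with ``d0 + d_g`` degrees of freedom; FDR is
    Benjamini-Hochberg.

    Genes with any missing value are dropped from the test.  Returns a
    DataFrame indexed by gene with columns ``log_fc`` (HFD - LFD, log2),
    ``t``, ``p_value``, ``fdr``.
    """
    if prior_df < 0:
        raise ValueError("prior_df must be nonnegative")
    if len(expr.timepoints()) > 1:
        raise ValueError(
            "expression matrix spans several timepoints; subset() first"
        )
    cols_a = expr.group_columns("HFD")
    cols_b = expr.group_columns("LFD")
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ValueError(f"need >=2 samples per group, got HFD={na}, LFD={nb}")

    vals = expr.values
    complete = vals.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} genes with missing values")
    vals = vals.loc[complete]
    if not np.isfinite(vals.to_numpy()).all():
        raise ValueError("expression values must be finite")

    a = vals[cols_a].to_numpy(float)
    b = vals[cols_b].to_numpy(float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    dg = na + nb - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / dg

    if prior_var is None:
        s0_2 = float(s2.mean())
    else:
        if prior_var < 0:
            raise ValueError("prior_var must be nonnegative")
        s0_2 = float(prior_var)

    if np.isinf(prior_df):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (prior_df * s0_2 + dg * s2) / (prior_df + dg)
        df_total = prior_df + dg

    diff = mean_a - mean_b
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled + zero prior variance: the statistic is undefined
    undefined = se == 0
    t = np.where(undefined & (diff == 0), np.nan, t)
    if np.any(undefined):
        warnings.warn(
            f"{int(undefined.sum())} genes have zero variance and an "
            "undefined t; reported as NaN"
        )
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df_total))
    p = np.where(np.isinf(t), 0.0, p)

    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])

    return pd.DataFrame(
        {"log_fc": diff, "t": t, "p_value": p, "fdr": fdr}, index=vals.index
    )
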