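"""Spearman correlation of physiological parameters with gene expression.

Each physiological parameter (body-mass gain, eWAT weight, energy
intake, ...) is correlated per animal against every gene's expression at
one timepoint, pooling both diet groups.  A gene belongs to a
parameter's backing set when |rho| exceeds ``rho_cutoff`` (default 0.8)
and the two-sided p value is below ``alpha`` (default 0.05); a parameter
is "linked" when its set is nonempty.  No multiple-testing correction is
applied on the gene x parameter grid — the dual |rho|/p cutoff is the
filtering rule as such.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionMatrix

__all__ = ["spearman", "correlate_parameters"]

_TINY_P = np.finfo(float).tiny


def _snap(rho: np.ndarray) -> np.ndarray:
    """Clamp to [-1, 1] and snap float-noise near-unit values to +/-1."""
    rho = np.clip(rho, -1.0, 1.0)
    return np.where(1.0 - np.abs(rho) < 1e-12, np.sign(rho), rho)


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation with n-2 df.

    |rho| = 1 is reported as the smallest positive float rather than 0.
    """
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, _TINY_P, p)
    return np.where(np.isnan(rho), np.nan, p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either argument are dropped first.
    Requires n >= 4 complete pairs; zero rank variance in either
    argument is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need >=4 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in ranks; rho undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = _snap(np.array([rho]))[0]
    p = float(_spearman_p(np.array([rho]), n)[0])
    return rho, p


def correlate_parameters(
    expr: ExpressionMatrix,
    physio: pd.DataFrame,
    rho_cutoff: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every parameter against every gene across shared animals.

    Parameters
    ----------
    expr
        Expression restricted to one timepoint; sample ids double as
        animal ids.
    physio
        DataFrame indexed by animal id, one numeric column per
        physiological parameter (a ``timepoint`` column, if present, is
        ignored as a parameter).  Missing values are handled
        pairwise-complete per parameter.

    Returns a long DataFrame (``parameter``, ``gene``, ``rho``,
    ``p_value``) holding only the pairs that pass both cutoffs; its
    ``attrs["parameters"]`` lists every tested parameter with its
    significant-gene count.
    """
    if len(expr.timepoints()) > 1:
        raise ValueError("expression spans several timepoints; subset() first")
    animals = [c for c in expr.values.columns if c in set(physio.index)]
    if len(animals) < 4:
        raise ValueError(
            f"need >=4 animals shared between tables, got {len(animals)}"
        )
    params = [c for c in physio.columns if c != "timepoint"]
    vals = expr.values[animals].to_numpy(float)
    genes = expr.values.index.to_numpy()

    rows: list[tuple[str, str, float, float]] = []
    summary: list[tuple[str, int]] = []
    for param in params:
        pv = physio.loc[animals, param].to_numpy(float)
        keep = ~np.isnan(pv)
        n = int(keep.sum())
        if n < 4:
            warnings.warn(f"parameter {param!r}: only {n} complete animals; skipped")
            summary.append((param, 0))
            continue
        rp = stats.rankdata(pv[keep])
        if rp.std() == 0:
            warnings.warn(f"parameter {param!r}: constant values; skipped")
            summary.append((param, 0))
            continue
        rg = np.apply_along_axis(stats.rankdata, 1, vals[:, keep])
        rg_c = rg - rg.mean(axis=1, keepdims=True)
        rp_c = rp - rp.mean()
        denom = np.sqrt((rg_c**2).sum(axis=1)) * np.sqrt((rp_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rg_c @ rp_c) / denom
        rho = _snap(rho)
        p = _spearman_p(rho, n)
        hit = (~np.isnan(rho)) & (np.abs(rho) > rho_cutoff) & (p < alpha)
        for g, r, q in zip(genes[hit], rho[hit], p[hit]):
            rows.append((param, g, float(r), float(q)))
        summary.append((param, int(hit.sum())))

    out = pd.DataFrame(rows, columns=["parameter", "gene", "rho", "p_value"])
    out = out.sort_values(["parameter", "gene"], ignore_index=True)
    out.attrs["parameters"] = summary
    return out


def parameter_gene_sets(correlations: pd.DataFrame) -> dict[str, frozenset]:
    """Backing gene set per linked (nonempty) parameter."""
    return {
        param: frozenset(sub["gene"])
        for param, sub in correlations.groupby("parameter")
        if len(sub)
    }
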