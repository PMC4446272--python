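"""Preranked gene-set enrichment on differential-expression t scores.

A gene set's enrichment score (ES) is the signed maximal deviation of a
running sum walked down the t-ranked gene list: hitting a member adds
|t|^p / N_R (N_R normalises hit weights to 1), missing subtracts
1/(N - N_H).  Significance comes from a gene-sampling permutation null:
random sets of the same size drawn from the ranked universe.

Two statistics are available:

``signed`` (default)
    ES = running-sum value of maximal absolute deviation, p computed
    against same-sign null ES values.  This is the standard preranked
    GSEA statistic.
``pos``
    ES = maximal (positive) running-sum value only.  Running the ranking
    forward and reversed with this one-sided statistic lets a set be
    significantly enriched at *both* extremes — the basis of the
    up/down/both direction labels used for network node colouring.

Node scores for the process layer are -log10(p) signed by direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GseaConfig",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "classify_direction",
]


@dataclass(frozen=True)
class RankedList:
    """Genes in descending score order with their scores."""

    genes: tuple[str, ...]
    scores: np.ndarray  # aligned with genes, descending

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(self.genes) == 0:
            raise ValueError("ranked list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be nonincreasing")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed(self) -> "RankedList":
        """The negated-score, reversed-order ranking (bottom first)."""
        return RankedList(self.genes[::-1], -self.scores[::-1])


@dataclass(frozen=True)
class GseaConfig:
    min_size: int = 15
    max_size: int = 500
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    statistic: str = "signed"  # "signed" | "pos"

    def __post_init__(self) -> None:
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")
        if self.n_permutations < 100:
            raise ValueError("need n_permutations >= 100")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be nonnegative")
        if self.statistic not in ("signed", "pos"):
            raise ValueError("statistic must be 'signed' or 'pos'")


def rank_genes(de: pd.DataFrame) -> RankedList:
    """Order genes by descending t score; ties break lexically by id."""
    if len(de) == 0:
        raise ValueError("empty DE result")
    t = de["t"]
    if not np.isfinite(t.to_numpy(float)).all():
        raise ValueError("t scores must be finite")
    order = sorted(de.index, key=lambda g: (-t[g], g))
    return RankedList(tuple(order), t.loc[order].to_numpy(float))


def _es_from_hits(
    pos: np.ndarray, w: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """Signed and one-sided ES from sorted 0-based hit positions.

    ``pos`` and ``w`` are (m, k): m instances of a k-gene set, hit
    positions ascending, ``w`` the |score|^p weights at those positions.
    The running sum only changes slope at hits, so its extrema sit just
    after a hit (maxima) or just before one (minima); both families are
    evaluated in closed form without walking the full list.
    """
    m, k = pos.shape
    if k >= n_total:
        raise ValueError("gene set must not cover the whole universe")
    nr = w.sum(axis=1)
    if np.any(nr == 0):
        raise ValueError("all hit weights are zero; ES undefined")
    miss_step = 1.0 / (n_total - k)
    cw = np.cumsum(w, axis=1) / nr[:, None]
    j = np.arange(k)
    miss_before = (pos - j) * miss_step  # misses strictly before hit j
    after = cw - miss_before  # running sum right after hit j
    before = np.concatenate(
        [np.zeros((m, 1)), cw[:, :-1]], axis=1
    ) - miss_before  # right before hit j
    max_pos = after.max(axis=1)
    min_neg = before.min(axis=1)
    # at an exact magnitude tie the positive deviation wins
    signed = np.where(max_pos >= -min_neg, max_pos, min_neg)
    return signed, max_pos


def enrichment_score(
    ranked: RankedList, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, frozenset]:
    """Running-sum ES of one gene set against one ranking.

    Returns ``(ES, running_sum, leading_edge)`` where ``running_sum``
    has one value per list position (after processing that position)
    and the leading edge holds the members up to the extremum (positive
    ES) or after it (negative ES).
    """
    members = frozenset(gene_set)
    universe = ranked.genes
    n = len(universe)
    hits = np.fromiter((g in members for g in universe), bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == n:
        raise ValueError("gene set covers the whole universe")
    w = np.abs(ranked.scores) ** weight_exponent
    nr = w[hits].sum()
    if nr == 0:
        raise ValueError("all hit weights are zero; ES undefined")
    steps = np.where(hits, w / nr, 0.0) - np.where(hits, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = frozenset(
            g for i, g in enumerate(universe) if hits[i] and i <= i_max
        )
    else:
        es = float(running[i_min])
        leading = frozenset(
            g for i, g in enumerate(universe) if hits[i] and i > i_min
        )
    return es, running, leading


def _null_es(
    rng: np.random.Generator,
    weights: np.ndarray,
    k: int,
    n_perm: int,
    statistic: str,
) -> np.ndarray:
    """Null ES for random k-subsets of an N-gene universe."""
    n = weights.size
    r = rng.random((n_perm, n))
    idx = np.argpartition(r, k, axis=1)[:, :k]
    pos = np.sort(idx, axis=1)
    signed, max_pos = _es_from_hits(pos, weights[pos], n)
    return max_pos if statistic == "pos" else signed


def gsea_preranked(
    ranked: RankedList, collection: dict, cfg: GseaConfig
) -> pd.DataFrame:
    """Permutation GSEA of a gene-set collection against one ranking.

    Sets are first intersected with the ranked universe and filtered to
    effective sizes in [min_size, max_size].  For each surviving set the
    null is built from ``n_permutations`` random same-size subsets; the
    p value uses (n_exceed + 1)/(n_tail + 1) smoothing, NES divides ES
    by the mean magnitude of same-sign null ES, and the FDR q follows
    the GSEA null-vs-observed NES tail-ratio convention.

    Returns a DataFrame sorted by p with columns
    ``set, size, es, nes, p_value, fdr_q``.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    universe = set(ranked.genes)
    n = len(ranked)
    effective: dict[str, frozenset] = {}
    for name in sorted(collection):
        members = frozenset(collection[name]) & universe
        if cfg.min_size <= len(members) <= cfg.max_size and len(members) < n:
            effective[name] = members
    if not effective:
        warnings.warn("no gene set survives the size filter")
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p_value", "fdr_q"]
        )

    weights = np.abs(ranked.scores) ** cfg.weight_exponent
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    rng = np.random.default_rng(cfg.seed)

    names = sorted(effective)
    sizes = {name: len(effective[name]) for name in names}
    by_size: dict[int, list[str]] = {}
    for name in names:
        by_size.setdefault(sizes[name], []).append(name)

    es_obs: dict[str, float] = {}
    nulls: dict[str, np.ndarray] = {}
    for k in sorted(by_size):
        null_k = _null_es(rng, weights, k, cfg.n_permutations, cfg.statistic)
        for name in by_size[k]:
            pos = np.sort([gene_pos[g] for g in effective[name]])[None, :]
            signed, max_pos = _es_from_hits(pos, weights[pos], n)
            es_obs[name] = float(
                max_pos[0] if cfg.statistic == "pos" else signed[0]
            )
            nulls[name] = null_k

    # p values and NES per set
    rows = []
    obs_nes = {}
    null_nes_pool = []
    for name in names:
        es = es_obs[name]
        null = nulls[name]
        if cfg.statistic == "pos":
            n_exc = int((null >= es).sum())
            p = (n_exc + 1) / (null.size + 1)
            scale = null.mean()
            nes = es / scale if scale > 0 else np.nan
            null_nes_pool.append(null / scale if scale > 0 else null * np.nan)
        else:
            pos_null = null[null > 0]
            neg_null = null[null < 0]
            mean_pos = pos_null.mean() if pos_null.size else np.nan
            mean_neg = np.abs(neg_null.mean()) if neg_null.size else np.nan
            if es >= 0:
                n_exc = int((pos_null >= es).sum())
                p = (n_exc + 1) / (pos_null.size + 1)
                nes = es / mean_pos if mean_pos > 0 else np.nan
            else:
                n_exc = int((neg_null <= es).sum())
                p = (n_exc + 1) / (neg_null.size + 1)
                nes = es / mean_neg if mean_neg > 0 else np.nan
            pooled = np.concatenate(
                [
                    pos_null / mean_pos if pos_null.size else pos_null,
                    neg_null / mean_neg if neg_null.size else neg_null,
                ]
            )
            null_nes_pool.append(pooled)
        obs_nes[name] = nes
        rows.append((name, sizes[name], es, nes, p))

    pool = np.concatenate(null_nes_pool)
    pool = pool[~np.isnan(pool)]
    obs = np.array([obs_nes[name] for name in names])
    qs = {}
    for name in names:
        nes = obs_nes[name]
        if np.isnan(nes):
            qs[name] = np.nan
            continue
        if nes >= 0:
            null_tail = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
            obs_tail = (obs >= nes).sum() / max((obs >= 0).sum(), 1)
        else:
            null_tail = (pool <= nes).sum() / max((pool < 0).sum(), 1)
            obs_tail = (obs <= nes).sum() / max((obs < 0).sum(), 1)
        qs[name] = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else np.nan

    out = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p_value"]
    )
    out["fdr_q"] = [qs[name] for name in out["set"]]
    out = out.sort_values(["p_value", "set"], ignore_index=True)
    log.info(
        "gsea: %d/%d sets in [%d, %d], %d permutations",
        len(effective), len(collection), cfg.min_size, cfg.max_size,
        cfg.n_permutations,
    )
    return out


def classify_direction(
    records_fwd: pd.DataFrame, records_rev: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Merge forward- and reversed-ranking runs into directed records.

    A run "supports" a set when its p < alpha with positive ES.  Support
    in the forward run only → ``up``; in the reversed run only (or a
    significant negative forward ES) → ``down``; in both → ``both``.
    The node score is -log10 of the supporting p, negative for ``down``.
    Sets significant in neither run keep a provisional label from the
    forward ES sign with ``significant = False``.
    """
    fwd = records_fwd.set_index("set")
    rev = records_rev.set_index("set")
    if set(fwd.index) != set(rev.index):
        raise ValueError("forward and reverse runs cover different sets")
    rows = []
    for name in fwd.index.sort_values():
        pf, ef = float(fwd.at[name, "p_value"]), float(fwd.at[name, "es"])
        pr, er = float(rev.at[name, "p_value"]), float(rev.at[name, "es"])
        fwd_pos = pf < alpha and ef > 0
        rev_pos = pr < alpha and er > 0
        fwd_neg = pf < alpha and ef < 0
        if fwd_pos and rev_pos:
            direction, p, sig = "both", min(pf, pr), True
        elif fwd_pos:
            direction, p, sig = "up", pf, True
        elif rev_pos or fwd_neg:
            direction, p, sig = "down", min(pr, pf if fwd_neg else 1.0), True
        else:
            direction, p, sig = ("up" if ef > 0 else "down"), min(pf, pr), False
        score = -np.log10(p) * (-1.0 if direction == "down" else 1.0)
        rows.append(
            (
                name, int(fwd.at[name, "size"]), ef, pf, er, pr,
                direction, sig, p, score,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set", "size", "es_fwd", "p_fwd", "es_rev", "p_rev",
            "direction", "significant", "p_value", "node_score",
        ],
    )
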