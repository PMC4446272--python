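"""Transcription-factor regulon enrichment among differentially expressed genes.

For each TF, targets are intersected with the tested gene universe and
scored for over-representation among the FDR-significant DE genes with a
one-sided hypergeometric test.  Directionality is the activation
z-score z = (n_up - n_down) / sqrt(n_up + n_down) over the DE targets,
and the activation score is -log10(p) carrying the sign of z.  TFs with
identical DE target sets collapse into one cluster whose representative
is the most significant member.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["regulon_enrichment", "cluster_regulators"]


def regulon_enrichment(
    de: pd.DataFrame,
    regulons: dict,
    fdr_cutoff: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every regulon for enrichment among DE genes.

    Parameters
    ----------
    de
        Differential-expression result indexed by gene with columns
        ``log_fc`` and ``fdr``; its index is the tested universe.
    regulons
        Mapping TF name -> iterable of target genes.
    fdr_cutoff
        DE gene definition (FDR < cutoff).
    alpha
        Significance flag threshold on the hypergeometric p.

    Returns a DataFrame with one row per TF: ``tf, n_targets, n_de,
    n_up, n_down, p_value, z, activation_score, significant,
    de_targets`` (the last a sorted tuple, the regulator's backing set).
    """
    universe = set(de.index)
    if not universe:
        raise ValueError("empty gene universe")
    if not regulons:
        raise ValueError("empty regulon collection")
    de_genes = set(de.index[de["fdr"] < fdr_cutoff])
    up_genes = set(de.index[(de["fdr"] < fdr_cutoff) & (de["log_fc"] > 0)])
    m_total = len(universe)
    n_de = len(de_genes)

    rows = []
    for tf in sorted(regulons):
        targets = set(regulons[tf]) & universe
        if not targets:
            warnings.warn(f"regulon {tf!r} has no targets in the universe")
            rows.append((tf, 0, 0, 0, 0, 1.0, 0.0, 0.0, False, ()))
            continue
        de_targets = targets & de_genes
        k = len(de_targets)
        # P(X >= k), X ~ Hypergeom(M=m_total, K=n_de, n=|targets|)
        p = float(stats.hypergeom.sf(k - 1, m_total, n_de, len(targets)))
        p = min(p, 1.0)
        n_up = len(de_targets & up_genes)
        n_down = k - n_up
        z = (n_up - n_down) / np.sqrt(k) if k > 0 else 0.0
        activation = -np.log10(p) * np.sign(z)
        rows.append(
            (
                tf, len(targets), k, n_up, n_down, p, float(z),
                float(activation), p < alpha, tuple(sorted(de_targets)),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "tf", "n_targets", "n_de", "n_up", "n_down", "p_value", "z",
            "activation_score", "significant", "de_targets",
        ],
    )
    log.info(
        "regulators: %d/%d TFs significant at p<%g (universe %d, DE %d)",
        int(out["significant"].sum()), len(out), alpha, m_total, n_de,
    )
    return out


def cluster_regulators(
    records: pd.DataFrame, key: str = "de_targets"
) -> pd.DataFrame:
    """Cluster TFs whose target sets coincide exactly.

    ``key`` selects the clustering key: ``de_targets`` (default) merges
    TFs with identical DE-restricted target sets; ``targets`` would
    require full-target identity and must then be a column of tuples in
    ``records``.  The representative of each cluster is the member with
    the smallest enrichment p (ties broken by TF name); only
    representatives become network nodes, but every TF stays in the
    table.  The operation is idempotent.
    """
    if key not in records.columns:
        raise ValueError(f"no column {key!r} to cluster on")
    out = records.copy()
    groups: dict[tuple, list[int]] = {}
    for i, row in out.iterrows():
        groups.setdefault(tuple(row[key]), []).append(i)

    cluster_ids = {}
    representatives = {}
    # deterministic cluster numbering: by representative (p, name)
    reps = []
    for members in groups.values():
        rep = min(members, key=lambda i: (out.at[i, "p_value"], out.at[i, "tf"]))
        reps.append((out.at[rep, "p_value"], out.at[rep, "tf"], rep, members))
    for n, (_, _, rep, members) in enumerate(sorted(reps, key=lambda r: (r[0], r[1])), 1):
        cid = f"C{n:03d}"
        for i in members:
            cluster_ids[i] = cid
            representatives[i] = i == rep
    out["cluster"] = [cluster_ids[i] for i in out.index]
    out["is_representative"] = [representatives[i] for i in out.index]
    log.info(
        "regulators: %d TFs in %d clusters", len(out), len(groups)
    )
    return out
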