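"""Gene-set enrichment: hypergeometric over-representation and preranked GSEA.

ORA tests each annotation set for over-representation among a hit list via
the exact hypergeometric upper tail with BH correction across sets.  The
preranked GSEA implements the classic weighted Kolmogorov-Smirnov running
sum with a gene-label permutation null, signed-mean NES normalization and
the standard pooled-NES FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_bh


def ora_hypergeometric(hits: set[str], universe: set[str],
                       sets: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    Sets are intersected with the universe; p = P(X >= overlap) for the
    hypergeometric draw of |hits| from |universe| with |set| successes; q is
    BH-adjusted across sets.  Sorted by p then set name.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & universe
        overlap = len(members & hits)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                     len(members), len(hits)))
        rows.append({"set": name, "set_size": len(members),
                     "overlap": overlap, "p": p})
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    table["q"] = adjust_bh(table["p"].to_numpy()) if len(table) else []
    return table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def _rank_order(ranked: pd.Series) -> pd.Series:
    """Descending metric, ties broken by id for determinism."""
    frame = ranked.rename("metric").rename_axis("id").reset_index()
    frame = frame.sort_values(["metric", "id"], ascending=[False, True],
                              kind="mergesort")
    return pd.Series(frame["metric"].to_numpy(), index=frame["id"].to_numpy())


def gsea_enrichment_score(ranked: pd.Series, gene_set: set[str],
                          weight: float = 1.0) -> tuple[float, np.ndarray, int]:
    """Weighted KS enrichment score of a gene set on a ranked list.

    ``ranked`` maps unique ids to ranking-metric values (any order; sorted
    descending internally, ties by id).  Hits add |metric|^weight
    normalized by the hit total; misses subtract 1/(N - N_hits).  Returns
    (es, running sum, index of the signed extreme).
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked ids must be unique")
    ordered = _rank_order(ranked)
    is_hit = ordered.index.isin(set(gene_set))
    n_hits = int(is_hit.sum())
    n = len(ordered)
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list (no misses)")
    hit_w = np.abs(ordered.to_numpy(dtype=float)) ** weight
    hit_w = np.where(is_hit, hit_w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-zero metric among hits: fall back to equal weights
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~is_hit).astype(float) / (n - n_hits)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    size: int


def gsea_preranked(ranked: pd.Series, sets: dict[str, list[str]],
                   n_permutations: int = 1000, seed: int = 0,
                   weight: float = 1.0) -> list[GseaResult]:
    """Preranked GSEA with a gene-label permutation null.

    For every set the null ES distribution comes from random same-size
    subsets of the ranked ids; NES = ES / mean(|null ES| of matching sign),
    p is the matching-sign permutation tail, and FDR q follows the standard
    pooled positive/negative NES procedure.  Deterministic at fixed seed.
    Sets that do not intersect the ranked list are skipped.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    ordered = _rank_order(ranked)
    ids = ordered.index.to_numpy()
    n = len(ids)
    absw = np.abs(ordered.to_numpy(dtype=float)) ** weight

    def _es(is_hit: np.ndarray) -> float:
        n_hits = int(is_hit.sum())
        hit_w = np.where(is_hit, absw, 0.0)
        total = hit_w.sum()
        if total == 0:
            hit_w = is_hit.astype(float)
            total = float(n_hits)
        running = np.cumsum(hit_w / total - (~is_hit) / (n - n_hits))
        return float(running[np.argmax(np.abs(running))])

    obs: dict[str, tuple[float, int]] = {}
    null_es: dict[str, np.ndarray] = {}
    for name in sorted(sets):
        members = set(sets[name]) & set(ids)
        if not members or len(members) >= n:
            continue
        size = len(members)
        es = _es(np.isin(ids, list(members)))
        nulls = np.empty(n_permutations)
        for b in range(n_permutations):
            is_hit = np.zeros(n, dtype=bool)
            is_hit[rng.choice(n, size=size, replace=False)] = True
            nulls[b] = _es(is_hit)
        obs[name] = (es, size)
        null_es[name] = nulls

    # signed-mean normalization of observed and null scores
    nes_obs: dict[str, float] = {}
    nes_null: dict[str, np.ndarray] = {}
    pvals: dict[str, float] = {}
    for name, (es, _) in obs.items():
        nulls = null_es[name]
        pos = nulls[nulls >= 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan

        def _norm(value: float) -> float:
            if value >= 0:
                return value / mean_pos if mean_pos and not np.isnan(mean_pos) else 0.0
            return value / mean_neg if mean_neg and not np.isnan(mean_neg) else 0.0

        nes_obs[name] = _norm(es)
        nes_null[name] = np.array([_norm(x) for x in nulls])
        same = pos if es >= 0 else neg
        if same.size == 0:
            pvals[name] = 1.0 / (nulls.size + 1)
        else:
            extreme = (np.abs(same) >= abs(es)).sum()
            pvals[name] = max(float(extreme) / same.size, 1.0 / (nulls.size + 1))

    all_null = np.concatenate(list(nes_null.values())) if nes_null else np.array([])
    all_obs = np.array(list(nes_obs.values()))
    results = []
    for name, (es, size) in obs.items():
        nes = nes_obs[name]
        if nes >= 0:
            null_frac = (all_null >= nes).mean() if all_null.size else 1.0
            obs_frac = (all_obs >= nes).mean()
        else:
            null_frac = (all_null <= nes).mean() if all_null.size else 1.0
            obs_frac = (all_obs <= nes).mean()
        q = 1.0 if obs_frac == 0 else min(null_frac / obs_frac, 1.0)
        results.append(GseaResult(set_name=name, es=es, nes=nes,
                                  p=pvals[name], fdr_q=q, size=size))
    results.sort(key=lambda r: (r.p, -abs(r.nes), r.set_name))
    return results
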