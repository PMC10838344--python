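"""FlipTF discovery: preranked regulon enrichment with a permutation-normalized score.

Genes are ranked by flip evidence (see :func:`flipmoa.flip.flip_score`) and
each transcription factor's regulon is scored by the weighted
Kolmogorov-Smirnov running-sum enrichment score familiar from preranked
GSEA: walking down the ranking, the sum gains |weight|^exponent (normalized
over the regulon's hits) at each regulon gene and loses 1/(N - hits) at each
non-member; the enrichment score ES is the signed extreme deviation. The
null is gene-label permutation: random same-size regulons drawn from the
ranked universe. NES divides ES by the mean magnitude of sign-matched null
scores, and the permutation p-value uses the add-one rule so it is never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import bh_adjust
from .io import GeneSetCollection

__all__ = ["ranked_list", "enrichment_score", "nes_permutation", "score_regulons"]


def ranked_list(scores: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Order genes by descending score, ties broken by gene id.

    Returns (gene array, weight array). NaN scores are rejected.
    """
    if scores.isna().any():
        bad = scores.index[scores.isna()][0]
        raise ValueError(f"NaN score for gene {bad!r}")
    df = pd.DataFrame({"gene": scores.index.astype(str), "score": scores.to_numpy(float)})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return df["gene"].to_numpy(), df["score"].to_numpy()


def _hit_mask(genes: np.ndarray, regulon) -> np.ndarray:
    reg = set(regulon)
    return np.fromiter((g in reg for g in genes), bool, len(genes))


def enrichment_score(
    genes: np.ndarray,
    weights: np.ndarray,
    regulon,
    weight_exponent: float = 0.0,
) -> float:
    """Signed extreme deviation of the weighted KS running sum.

    With ``weight_exponent`` 0 the walk reduces to the classical KS
    statistic and is invariant to monotone rescaling of the weights. If all
    hit weights are zero the hit increments fall back to equal steps.
    """
    hits = _hit_mask(genes, regulon)
    m = int(hits.sum())
    N = len(genes)
    if m == 0 or m == N:
        raise ValueError("regulon must hit a strict, non-empty subset of the ranking")
    w = np.abs(weights[hits]) ** weight_exponent
    total = w.sum()
    if total <= 0:
        w = np.ones(m)
        total = float(m)
    step = np.where(hits, 0.0, -1.0 / (N - m))
    step[hits] = w / total
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _null_es(
    weights_sorted: np.ndarray,
    regulon_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """ES of ``n_perm`` random same-size regulons against a fixed ranking.

    Vectorized: each permutation is a set of hit positions; the running sum
    is evaluated analytically just before and after each hit, where its
    extremes occur.
    """
    N = len(weights_sorted)
    m = regulon_size
    absw = np.abs(weights_sorted) ** weight_exponent
    # distinct sorted hit positions per permutation
    pos = np.empty((n_perm, m), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = rng.choice(N, size=m, replace=False)
    pos.sort(axis=1)

    w = absw[pos]  # (n_perm, m)
    totals = w.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] <= 0
    w = np.where(degenerate[:, None], 1.0 / m, w / np.where(totals > 0, totals, 1.0))
    gains = np.cumsum(w, axis=1)
    d = 1.0 / (N - m)
    ranks = np.arange(m)[None, :]
    # value just before hit j: gains up to j-1 minus misses seen so far
    before = np.concatenate([np.zeros((n_perm, 1)), gains[:, :-1]], axis=1) - (
        pos - ranks
    ) * d
    after = before + w
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    es = np.where(hi >= -lo, hi, lo)
    return es


def nes_permutation(
    es: float,
    genes: np.ndarray,
    weights: np.ndarray,
    regulon_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 0.0,
) -> tuple[float, float]:
    """Normalize an ES against a gene-label permutation null.

    nes = es / mean(|null ES| of matching sign); p = (1 + #{null at least
    as extreme, same sign}) / (n_perm + 1). Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    null = _null_es(weights, regulon_size, n_perm, rng, weight_exponent)
    if np.allclose(null, 0.0):
        raise ValueError("degenerate permutation null: all null ES are zero")
    if es > 0:
        denom = np.abs(null[null > 0]).mean() if (null > 0).any() else np.abs(null).mean()
        p = (1 + int((null >= es).sum())) / (n_perm + 1)
        nes = es / denom
    elif es < 0:
        denom = np.abs(null[null < 0]).mean() if (null < 0).any() else np.abs(null).mean()
        p = (1 + int((null <= es).sum())) / (n_perm + 1)
        nes = -abs(es) / denom
    else:
        nes = 0.0
        p = (1 + int((null >= 0).sum())) / (n_perm + 1)
    return float(nes), float(p)


def score_regulons(
    scores: pd.Series,
    regulons: GeneSetCollection,
    weight_exponent: float = 0.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    flip_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score every regulon against the flip ranking; BH across TFs.

    Regulons with fewer than ``min_size`` genes in the ranked universe are
    skipped. ``flip_classes`` (gene -> 'up_down'/'down_up') optionally
    labels each TF with the flip class that dominates its regulon, mirroring
    the two-sided presentation of flip TFs. Returns a DataFrame indexed by
    TF with es, nes, p, fdr, regulon_size, direction.
    """
    genes, weights = ranked_list(scores)
    universe = set(genes)
    rows = []
    ss = np.random.SeedSequence(seed)
    tf_ids = sorted(regulons.sets)
    child_seeds = ss.generate_state(len(tf_ids))
    for tf, sub_seed in zip(tf_ids, child_seeds):
        members = [g for g in regulons.members(tf) if g in universe]
        if len(members) < min_size:
            continue
        es = enrichment_score(genes, weights, members, weight_exponent)
        nes, p = nes_permutation(
            es, genes, weights, len(members),
            n_perm=n_perm, seed=int(sub_seed), weight_exponent=weight_exponent,
        )
        direction = ""
        if flip_classes:
            counts = {"up_down": 0, "down_up": 0}
            for g in members:
                c = flip_classes.get(g)
                if c in counts:
                    counts[c] += 1
            if counts["up_down"] or counts["down_up"]:
                direction = max(counts, key=lambda c: (counts[c], c))
        rows.append((tf, es, nes, p, len(members), direction))
    df = pd.DataFrame(
        rows, columns=["tf", "es", "nes", "p", "regulon_size", "direction"]
    ).set_index("tf")
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df[["es", "nes", "p", "fdr", "regulon_size", "direction"]].sort_values(
        ["p", "tf"], kind="mergesort", ascending=[True, True]
    )
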