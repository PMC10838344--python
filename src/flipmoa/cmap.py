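"""Connectivity-map screen: which library drugs mimic the reference drug's flip?

Each drug profile is reduced to a signature of its most extreme genes
(default 100 up, 100 down). A profile mimics the flip signature when its
down-regulated flank recovers the Flip(Up->Down) genes and its up-regulated
flank recovers the Flip(Down->Up) genes; similarity is the Jaccard index.
Only high-quality profiles of FDA-approved drugs are screened. Profiles in
the top decile of Jaccard scores define the mimic drugs (a drug counts if
any of its retained profiles qualifies), and drug-target interactions are
then tested for enrichment among mimic drugs versus all screened drugs: the
target score is the enrichment factor (k/n)/(K/N) with a hypergeometric
p-value and BH correction across targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import bh_adjust
from .flip import FlipSet
from .io import DrugProfileLibrary, DrugTargetTable
from .pathways import hypergeom_tail

__all__ = [
    "DrugSignature",
    "make_signature",
    "jaccard",
    "mimicry_scores",
    "target_enrichment",
    "mimic_drugs",
    "flip_axis_summary",
]


@dataclass
class DrugSignature:
    """Top up- and down-regulated genes of one drug profile."""

    profile_id: str
    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        if len(self.up) != len(self.down):
            raise ValueError("up and down flanks must have equal size")
        if set(self.up) & set(self.down):
            raise ValueError("up and down flanks must be disjoint")


def make_signature(scores: pd.Series, n_sig: int = 100, profile_id: str = "") -> DrugSignature:
    """Extract the n_sig most up- and down-regulated genes of a profile.

    Genes are ordered by (score, gene id) ascending: the down flank is the
    first block, the up flank the last, which makes ties deterministic.
    """
    if len(scores) < 2 * n_sig:
        raise ValueError(
            f"profile scores {len(scores)} genes; need at least {2 * n_sig}"
        )
    df = pd.DataFrame({"gene": scores.index.astype(str), "score": scores.to_numpy(float)})
    df = df.sort_values(["score", "gene"], kind="mergesort")
    down = df["gene"].iloc[:n_sig].tolist()
    up = df["gene"].iloc[-n_sig:].tolist()
    return DrugSignature(profile_id=profile_id, up=up, down=down)


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; 0 when both sets are empty (by convention)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def mimicry_scores(
    fs: FlipSet,
    lib: DrugProfileLibrary,
    mode: str = "directional",
    n_sig: int = 100,
    decile: float = 0.1,
) -> pd.DataFrame:
    """Jaccard similarity of every retained profile to the flip signature.

    ``directional`` counts only direction-concordant hits — signature-down
    genes among Flip(Up->Down) plus signature-up genes among Flip(Down->Up)
    — over the union of flip genes and signature genes; ``pooled`` ignores
    direction. The top ``decile`` of retained profiles (ties at the
    threshold included) is flagged. Returns a DataFrame indexed by
    profile_id with drug_id, jaccard, rank, in_top_decile.
    """
    if mode not in ("directional", "pooled"):
        raise ValueError("mode must be 'directional' or 'pooled'")
    retained = lib.retained()
    if not retained.profiles:
        raise ValueError("no profiles pass the quality/FDA filter")
    up_down = set(fs.up_down)
    down_up = set(fs.down_up)
    flip = up_down | down_up
    if not flip & set(lib.gene_space):
        raise ValueError("library gene space shares no genes with the flip signature")

    rows = []
    for pid in sorted(retained.profiles):
        prof = retained.profiles[pid]
        sig = make_signature(prof.scores, n_sig=n_sig, profile_id=pid)
        sig_genes = set(sig.up) | set(sig.down)
        if mode == "pooled":
            j = jaccard(flip, sig_genes)
        else:
            concordant = (set(sig.down) & up_down) | (set(sig.up) & down_up)
            union = flip | sig_genes
            j = len(concordant) / len(union) if union else 0.0
        rows.append((pid, prof.drug_id, j))
    df = pd.DataFrame(rows, columns=["profile_id", "drug_id", "jaccard"]).set_index(
        "profile_id"
    )
    df = df.sort_values(["jaccard", "profile_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    m = math.ceil(decile * len(df))
    threshold = df["jaccard"].iloc[m - 1]
    df["in_top_decile"] = df["jaccard"] >= threshold
    return df


def mimic_drugs(mim: pd.DataFrame) -> set[str]:
    """Drugs owning at least one top-decile profile."""
    return set(mim.loc[mim["in_top_decile"], "drug_id"])


def target_enrichment(mim: pd.DataFrame, targets: DrugTargetTable) -> pd.DataFrame:
    """Enrichment of each drug target among mimic drugs vs all screened drugs.

    k = mimic drugs annotated to the target, K = screened drugs annotated,
    n = mimic drugs, N = screened drugs; EF = (k/n)/(K/N), p from the
    hypergeometric upper tail, FDR by BH across targets. Targets with no
    screened annotated drug are skipped.
    """
    screened = set(mim["drug_id"])
    mimics = mimic_drugs(mim)
    N, n = len(screened), len(mimics)
    rows = []
    for target in sorted(set(targets.rows["target_id"])):
        annotated = targets.drugs_of(target) & screened
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & mimics)
        ef = (k / n) / (K / N) if n else 0.0
        p = hypergeom_tail(k, K, n, N)
        rows.append((target, k, K, ef, p))
    df = pd.DataFrame(
        rows, columns=["target_id", "n_mimic_hits", "n_total_hits", "ef", "p"]
    ).set_index("target_id")
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "target_id"], kind="mergesort")


def flip_axis_summary(
    fs: FlipSet, lib: DrugProfileLibrary, n_sig: int = 100
) -> pd.DataFrame:
    """Per-drug counts of flip genes hit in each direction (scatter axes).

    For each screened drug, the best profile's count of Flip(Up->Down) genes
    in its down flank (x) and Flip(Down-Up) genes in its up flank (y).
    """
    retained = lib.retained()
    up_down, down_up = set(fs.up_down), set(fs.down_up)
    per_drug: dict[str, list[int]] = {}
    for pid in sorted(retained.profiles):
        prof = retained.profiles[pid]
        sig = make_signature(prof.scores, n_sig=n_sig, profile_id=pid)
        x = len(set(sig.down) & up_down)
        y = len(set(sig.up) & down_up)
        best = per_drug.get(prof.drug_id)
        if best is None or x + y > best[0] + best[1]:
            per_drug[prof.drug_id] = [x, y]
    return pd.DataFrame(
        [(d, xy[0], xy[1]) for d, xy in sorted(per_drug.items())],
        columns=["drug_id", "n_up_down_hits", "n_down_up_hits"],
    ).set_index("drug_id")
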