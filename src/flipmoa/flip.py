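"""Flip-DEG classification: genes whose perturbation response a drug reverses.

Both contrasts are taken against the same untreated control. A gene is a
Flip(Up->Down) DEG if it is up under the perturbation rule in the
perturbation-vs-control contrast and down under the drug rule in the
drug-vs-control contrast; Flip(Down->Up) is the mirror class. Perturbation
DEGs that do not flip stay in the perturbed-only classes, so the flip and
perturbed-only classes exactly partition the perturbation DEGs of each sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import DEResult, DegRule, call_degs

__all__ = ["FlipSet", "classify_flip", "flip_fraction", "flip_score"]


@dataclass
class FlipSet:
    """The two flip classes plus the non-flipped perturbation DEGs."""

    up_down: list[str]
    down_up: list[str]
    perturbed_only_up: list[str]
    perturbed_only_down: list[str]
    rule_perturbed: DegRule | None = None
    rule_drug: DegRule | None = None

    def __post_init__(self) -> None:
        if set(self.up_down) & set(self.down_up):
            raise ValueError("a gene cannot be in both flip classes")

    @property
    def flip_genes(self) -> list[str]:
        return list(self.up_down) + list(self.down_up)

    def n_perturbed(self, direction: str) -> int:
        if direction == "up_down":
            return len(self.up_down) + len(self.perturbed_only_up)
        if direction == "down_up":
            return len(self.down_up) + len(self.perturbed_only_down)
        raise ValueError("direction must be 'up_down' or 'down_up'")

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(g, "up_down") for g in self.up_down]
            + [(g, "down_up") for g in self.down_up]
            + [(g, "perturbed_only_up") for g in self.perturbed_only_up]
            + [(g, "perturbed_only_down") for g in self.perturbed_only_down]
        )
        return pd.DataFrame(rows, columns=["gene", "class"])


def classify_flip(
    de_perturbed: DEResult,
    de_drug: DEResult,
    rule_perturbed: DegRule,
    rule_drug: DegRule,
) -> FlipSet:
    """Partition the perturbation DEGs into flipped and non-flipped classes.

    Flip membership requires the gene to pass the drug-contrast rule in the
    opposite direction, not merely to change sign.
    """
    if set(de_perturbed.genes) != set(de_drug.genes):
        diff = set(de_perturbed.genes) ^ set(de_drug.genes)
        raise ValueError(
            f"contrasts do not share a gene universe ({len(diff)} genes differ)"
        )
    calls_p = call_degs(de_perturbed, rule_perturbed)
    calls_d = call_degs(de_drug, rule_drug)

    up_down, down_up, only_up, only_down = [], [], [], []
    for g, direction in calls_p.items():
        drug_dir = calls_d.get(g)
        if direction == "up":
            (up_down if drug_dir == "down" else only_up).append(g)
        else:
            (down_up if drug_dir == "up" else only_down).append(g)
    return FlipSet(
        up_down=sorted(up_down),
        down_up=sorted(down_up),
        perturbed_only_up=sorted(only_up),
        perturbed_only_down=sorted(only_down),
        rule_perturbed=rule_perturbed,
        rule_drug=rule_drug,
    )


def flip_fraction(fs: FlipSet, direction: str) -> float:
    """Percentage of perturbation DEGs of one sign that the drug flipped.

    100 * |flip class| / |all perturbation DEGs of that sign|. Report with
    ``round()`` for the integer percent.
    """
    denom = fs.n_perturbed(direction)
    if denom == 0:
        raise ValueError(f"no perturbation DEGs in the {direction} denominator")
    num = len(fs.up_down) if direction == "up_down" else len(fs.down_up)
    return 100.0 * num / denom


def flip_score(de_perturbed: DEResult, de_drug: DEResult) -> pd.Series:
    """Per-gene flip evidence: drug fold change opposing the perturbation.

    score_g = -sign(log2fc_perturbed) * log2fc_drug where the two contrasts
    disagree in sign, else 0; larger means a stronger reversal. Used as the
    ranking metric for regulon enrichment.
    """
    if set(de_perturbed.genes) != set(de_drug.genes):
        raise ValueError("contrasts do not share a gene universe")
    lp = de_perturbed.table["log2fc"]
    ld = de_drug.table["log2fc"].reindex(lp.index)
    opposing = np.sign(lp) * np.sign(ld) < 0
    score = np.where(opposing, -np.sign(lp) * ld, 0.0)
    return pd.Series(score, index=lp.index, name="flip_score")
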