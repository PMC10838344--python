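"""Seeded generator for every input of the pipeline, with a ground-truth manifest.

Emulates the statistical structure of a three-condition bulk RNA-seq
experiment — untreated control, a strong transcriptomic perturbation (e.g.
receptor overexpression), and the perturbation plus a candidate reverting
drug — together with a pathway catalogue, TF regulons, a drug-signature
library, and a drug-target table with planted signal in each layer.

Counts are negative binomial with variance mu + dispersion * mu^2. Baseline
means are log-normal; planted perturbation genes shift by +/- perturb_lfc
(log2) in the perturbed condition; planted flip genes additionally cross
back past baseline in the drug condition so that the drug-vs-control
contrast is itself differential, in the opposite direction. Sample-specific
depth factors are uniform on [0.7, 1.3]. Every generator is a pure function
of its config: the same seed reproduces every artifact bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    DrugProfile,
    DrugProfileLibrary,
    DrugTargetTable,
    GeneSet,
    GeneSetCollection,
    TARGET_SOURCE_DBS,
    write_counts,
    write_drug_profiles,
    write_drug_targets,
    write_gmt,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_pathways",
    "simulate_regulons",
    "simulate_drug_library",
    "simulate_all",
    "write_all",
]


@dataclass
class PathwayPlan:
    n_decoys: int = 200
    n_planted: int = 1
    min_size: int = 10
    max_size: int = 50
    planted_flip_fraction: float = 0.7  # >= 0.6: planted sets drawn mostly from flips


@dataclass
class RegulonPlan:
    n_decoys: int = 50
    n_planted: int = 1
    min_size: int = 10
    max_size: int = 40
    planted_flip_fraction: float = 0.8


@dataclass
class LibraryPlan:
    n_drugs: int = 200
    profiles_per_drug: int = 2
    n_planted_mimics: int = 10
    mimic_overlap_fraction: float = 0.6
    n_sig: int = 100
    quality_rate: float = 0.7   # decoy profiles flagged high-quality
    fda_rate: float = 0.7       # decoy drugs flagged FDA-approved


@dataclass
class TargetPlan:
    n_targets: int = 50
    planted_target_coverage: float = 0.8
    background_rate: float = 0.05


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults mirroring the design."""

    n_genes: int = 2000
    n_per_condition: int = 5
    baseline_log_mean: float = 4.0   # natural-log scale of the log-normal mean
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    n_up_down: int = 80              # planted flips: up in perturbed, down after drug
    n_down_up: int = 120
    n_perturbed_only_up: int = 120
    n_perturbed_only_down: int = 180
    perturb_lfc: float = 3.0
    drug_revert_fraction: float = 1.0   # fraction of the perturbation undone
    drug_overshoot_lfc: float = 2.0     # log2 past baseline, so flips are clear drug DEGs
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    pathways: PathwayPlan = field(default_factory=PathwayPlan)
    regulons: RegulonPlan = field(default_factory=RegulonPlan)
    library: LibraryPlan = field(default_factory=LibraryPlan)
    targets: TargetPlan = field(default_factory=TargetPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_up_down
            + self.n_down_up
            + self.n_perturbed_only_up
            + self.n_perturbed_only_down
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene classes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if not 0 < self.drug_revert_fraction <= 1:
            raise ValueError("drug_revert_fraction must be in (0, 1]")
        for name in ("n_up_down", "n_down_up", "n_perturbed_only_up", "n_perturbed_only_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """What was planted where; the key for recovery checks."""

    gene_classes: dict[str, str]  # gene -> up_down | down_up | perturbed_only_up/down | null
    planted_pathways: list[str] = field(default_factory=list)
    planted_tfs: list[str] = field(default_factory=list)
    planted_mimic_drugs: list[str] = field(default_factory=list)
    planted_targets: list[str] = field(default_factory=list)

    def genes_of(self, cls: str) -> list[str]:
        return sorted(g for g, c in self.gene_classes.items() if c == cls)

    @property
    def flip_genes(self) -> list[str]:
        return sorted(
            g for g, c in self.gene_classes.items() if c in ("up_down", "down_up")
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_classes": self.gene_classes,
                "planted_pathways": self.planted_pathways,
                "planted_tfs": self.planted_tfs,
                "planted_mimic_drugs": self.planted_mimic_drugs,
                "planted_targets": self.planted_targets,
            },
            indent=1,
            sort_keys=True,
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB draw via gamma-Poisson mixture; variance = mean + dispersion*mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate the three-condition count matrix plus the gene-class manifest."""
    rng = _rng(cfg, 0)
    width = len(str(cfg.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)

    order = rng.permutation(cfg.n_genes)
    blocks = {
        "up_down": cfg.n_up_down,
        "down_up": cfg.n_down_up,
        "perturbed_only_up": cfg.n_perturbed_only_up,
        "perturbed_only_down": cfg.n_perturbed_only_down,
    }
    gene_classes = {g: "null" for g in genes}
    start = 0
    idx_of: dict[str, np.ndarray] = {}
    for cls, count in blocks.items():
        sel = order[start : start + count]
        idx_of[cls] = sel
        for i in sel:
            gene_classes[genes[i]] = cls
        start += count

    # log2 offsets per condition
    delta_pert = np.zeros(cfg.n_genes)
    delta_drug = np.zeros(cfg.n_genes)
    delta_pert[idx_of["up_down"]] = cfg.perturb_lfc
    delta_pert[idx_of["perturbed_only_up"]] = cfg.perturb_lfc
    delta_pert[idx_of["down_up"]] = -cfg.perturb_lfc
    delta_pert[idx_of["perturbed_only_down"]] = -cfg.perturb_lfc
    # non-flipped perturbation genes keep their shift under the drug
    delta_drug[idx_of["perturbed_only_up"]] = cfg.perturb_lfc
    delta_drug[idx_of["perturbed_only_down"]] = -cfg.perturb_lfc
    # flip genes revert and overshoot past baseline, in the opposite direction
    revert = cfg.drug_revert_fraction * cfg.perturb_lfc
    delta_drug[idx_of["up_down"]] = cfg.perturb_lfc - revert - cfg.drug_overshoot_lfc
    delta_drug[idx_of["down_up"]] = -cfg.perturb_lfc + revert + cfg.drug_overshoot_lfc

    n = cfg.n_per_condition
    sf = rng.uniform(*cfg.size_factor_range, 3 * n)
    deltas = np.concatenate(
        [np.zeros((cfg.n_genes, n)),
         np.repeat(delta_pert[:, None], n, axis=1),
         np.repeat(delta_drug[:, None], n, axis=1)],
        axis=1,
    )
    mean = mu[:, None] * (2.0 ** deltas) * sf[None, :]
    counts = _nb_sample(mean, cfg.dispersion, rng)

    samples = (
        [f"control_{j + 1}" for j in range(n)]
        + [f"perturbed_{j + 1}" for j in range(n)]
        + [f"perturbed_drug_{j + 1}" for j in range(n)]
    )
    condition = {s: s.rsplit("_", 1)[0] for s in samples}
    cm = CountMatrix(genes, samples, counts, condition)
    return cm, GroundTruth(gene_classes=gene_classes)


def _sample_set(
    rng: np.random.Generator,
    size: int,
    focus: list[str],
    rest: list[str],
    focus_fraction: float,
) -> list[str]:
    n_focus = min(int(round(focus_fraction * size)), len(focus))
    n_rest = size - n_focus
    picked = list(rng.choice(focus, n_focus, replace=False)) if n_focus else []
    picked += list(rng.choice(rest, n_rest, replace=False)) if n_rest else []
    return sorted(picked)


def simulate_pathways(cfg: SimConfig, gt: GroundTruth) -> GeneSetCollection:
    """Pathway catalogue: planted sets drawn mostly from flip genes, decoys uniform."""
    rng = _rng(cfg, 1)
    plan = cfg.pathways
    genes = sorted(gt.gene_classes)
    flips = gt.flip_genes
    if not flips and plan.n_planted:
        raise ValueError("cannot plant pathways without planted flip genes")
    non_flips = sorted(set(genes) - set(flips))
    sets: dict[str, GeneSet] = {}
    for i in range(plan.n_planted):
        size = int(rng.integers(plan.min_size, plan.max_size + 1))
        members = _sample_set(rng, size, flips, non_flips, plan.planted_flip_fraction)
        sets[f"PLANTED_PW_{i}"] = GeneSet("planted flip pathway", members)
    for i in range(plan.n_decoys):
        size = int(rng.integers(plan.min_size, plan.max_size + 1))
        members = sorted(rng.choice(genes, size, replace=False))
        sets[f"DECOY_PW_{i:03d}"] = GeneSet("decoy pathway", members)
    gt.planted_pathways = [f"PLANTED_PW_{i}" for i in range(plan.n_planted)]
    return GeneSetCollection(sets, universe=genes)


def simulate_regulons(cfg: SimConfig, gt: GroundTruth) -> GeneSetCollection:
    """TF regulons: planted regulons drawn mostly from flip genes, decoys uniform."""
    rng = _rng(cfg, 2)
    plan = cfg.regulons
    genes = sorted(gt.gene_classes)
    flips = gt.flip_genes
    if not flips and plan.n_planted:
        raise ValueError("cannot plant regulons without planted flip genes")
    non_flips = sorted(set(genes) - set(flips))
    sets: dict[str, GeneSet] = {}
    for i in range(plan.n_planted):
        size = int(rng.integers(plan.min_size, plan.max_size + 1))
        members = _sample_set(rng, size, flips, non_flips, plan.planted_flip_fraction)
        sets[f"PLANTED_TF_{i}"] = GeneSet("planted flip TF regulon", members)
    for i in range(plan.n_decoys):
        size = int(rng.integers(plan.min_size, plan.max_size + 1))
        members = sorted(rng.choice(genes, size, replace=False))
        sets[f"DECOY_TF_{i:03d}"] = GeneSet("decoy regulon", members)
    gt.planted_tfs = [f"PLANTED_TF_{i}" for i in range(plan.n_planted)]
    return GeneSetCollection(sets, universe=genes)


def simulate_drug_library(
    cfg: SimConfig, gt: GroundTruth
) -> tuple[DrugProfileLibrary, DrugTargetTable]:
    """Drug-signature library plus a drug-target table with one planted target.

    Decoy profiles score every gene N(0, 1). Planted mimic profiles push a
    ``mimic_overlap_fraction`` slice of each signature flank to extreme
    scores on direction-concordant flip genes: Flip(Up->Down) genes get
    strongly negative scores, Flip(Down->Up) strongly positive. Some decoy
    profiles are flagged low-quality and some decoy drugs non-FDA-approved
    to exercise the screening filter; planted mimics always pass it. The
    planted target annotates most mimic drugs and a small background rate of
    decoys; decoy targets annotate drugs at the background rate.
    """
    rng = _rng(cfg, 3)
    plan = cfg.library
    genes = sorted(gt.gene_classes)
    if len(genes) < 2 * plan.n_sig:
        raise ValueError("gene universe smaller than 2 * n_sig")
    up_down = gt.genes_of("up_down")
    down_up = gt.genes_of("down_up")
    if plan.n_planted_mimics and not (up_down or down_up):
        raise ValueError("cannot plant mimics without planted flip genes")
    if plan.n_planted_mimics > plan.n_drugs:
        raise ValueError("n_planted_mimics exceeds n_drugs")

    n_boost_down = min(int(round(plan.mimic_overlap_fraction * plan.n_sig)), len(up_down))
    n_boost_up = min(int(round(plan.mimic_overlap_fraction * plan.n_sig)), len(down_up))

    drug_ids = [f"DRUG_{i:03d}" for i in range(plan.n_drugs)]
    mimic_ids = drug_ids[: plan.n_planted_mimics]
    gidx = {g: i for i, g in enumerate(genes)}

    profiles: dict[str, DrugProfile] = {}
    for d_i, drug in enumerate(drug_ids):
        is_mimic = drug in set(mimic_ids)
        fda = True if is_mimic else bool(rng.random() < plan.fda_rate)
        for p_i in range(plan.profiles_per_drug):
            pid = f"{drug}_P{p_i}"
            scores = rng.normal(0.0, 1.0, len(genes))
            quality = True if is_mimic else bool(rng.random() < plan.quality_rate)
            if is_mimic:
                boost_dn = rng.choice(up_down, n_boost_down, replace=False)
                boost_up = rng.choice(down_up, n_boost_up, replace=False)
                for g in boost_dn:
                    scores[gidx[g]] = -(5.0 + rng.exponential(1.0))
                for g in boost_up:
                    scores[gidx[g]] = 5.0 + rng.exponential(1.0)
            profiles[pid] = DrugProfile(
                drug_id=drug,
                scores=pd.Series(scores, index=genes),
                quality=quality,
                fda_approved=fda,
            )
    lib = DrugProfileLibrary(profiles, genes)

    tplan = cfg.targets
    target_ids = [f"TARGET_{i:02d}" for i in range(tplan.n_targets)]
    planted_target = target_ids[0] if tplan.n_targets else None
    decoy_drugs = drug_ids[plan.n_planted_mimics :]
    rows = []
    dbs = list(TARGET_SOURCE_DBS)
    # fixed annotation counts: coverage/background are fractions, not rates
    n_bg = int(round(tplan.background_rate * len(decoy_drugs)))
    for t in target_ids:
        if t == planted_target:
            n_cov = int(round(tplan.planted_target_coverage * len(mimic_ids)))
            annotated = list(rng.choice(mimic_ids, n_cov, replace=False))
            annotated += list(rng.choice(decoy_drugs, n_bg, replace=False))
        else:
            annotated = list(rng.choice(drug_ids, n_bg, replace=False))
        for drug in annotated:
            rows.append((drug, t, dbs[int(rng.integers(len(dbs)))]))
    table = DrugTargetTable(
        pd.DataFrame(rows, columns=["drug_id", "target_id", "source_db"])
    )
    gt.planted_mimic_drugs = list(mimic_ids)
    gt.planted_targets = [planted_target] if planted_target else []
    return lib, table


def simulate_all(cfg: SimConfig):
    """Generate every pipeline input from one config; returns a dict bundle."""
    cm, gt = simulate_counts(cfg)
    pw = simulate_pathways(cfg, gt)
    reg = simulate_regulons(cfg, gt)
    lib, targets = simulate_drug_library(cfg, gt)
    return {
        "counts": cm,
        "ground_truth": gt,
        "pathways": pw,
        "regulons": reg,
        "library": lib,
        "targets": targets,
    }


def write_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write every simulated artifact to a directory (TSV/GMT/JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(cfg)
    write_counts(bundle["counts"], out / "counts.tsv", out / "conditions.tsv")
    write_gmt(bundle["pathways"], out / "pathways.gmt")
    write_gmt(bundle["regulons"], out / "regulons.gmt")
    write_drug_profiles(bundle["library"], out / "profiles.tsv", out / "profile_meta.tsv")
    write_drug_targets(bundle["targets"], out / "drug_targets.tsv")
    (out / "ground_truth.json").write_text(bundle["ground_truth"].to_json())
    return bundle
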