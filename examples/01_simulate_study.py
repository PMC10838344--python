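"""Generate a synthetic three-condition perturbation/rescue study.

The generator emulates a bulk RNA-seq experiment with an untreated control,
a strong transcriptomic perturbation, and the perturbation plus a reverting
drug, together with a pathway catalogue, TF regulons, a drug-signature
library and a drug-target table — each layer carrying planted signal
recorded in a ground-truth manifest.
"""

from flipmoa import SimConfig, simulate_all

cfg = SimConfig(seed=42)
bundle = simulate_all(cfg)

cm = bundle["counts"]
gt = bundle["ground_truth"]
print(f"count matrix: {cm.n_genes} genes x {cm.n_samples} samples")
print(f"conditions: {sorted(set(cm.condition.values()))}")
print(
    "planted gene classes:",
    {c: len(gt.genes_of(c)) for c in ("up_down", "down_up", "perturbed_only_up",
                                      "perturbed_only_down")},
)
print(f"pathways: {len(bundle['pathways'])} ({len(gt.planted_pathways)} planted)")
print(f"regulons: {len(bundle['regulons'])} ({len(gt.planted_tfs)} planted)")
print(f"drug profiles: {len(bundle['library'])}, planted mimic drugs: "
      f"{len(gt.planted_mimic_drugs)}")

# The planted up_down genes rise ~8-fold under the perturbation and are
# pushed back below baseline by the drug; everything downstream tries to
# rediscover exactly these genes from the counts alone.
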