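"""Classify flip DEGs: perturbation effects that the drug reverses.

A gene is Flip(Up->Down) when it is up in the perturbation-vs-control
contrast and down in the drug-vs-control contrast; Flip(Down->Up) is the
mirror. The flip fraction is the percentage of perturbation DEGs of each
sign that the drug flipped.
"""

from flipmoa import (
    DRUG_RULE,
    PERTURBATION_RULE,
    SimConfig,
    classify_flip,
    flip_fraction,
    flip_score,
    nb_wald_contrast,
    simulate_counts,
)

cm, gt = simulate_counts(SimConfig(seed=42))
de_p = nb_wald_contrast(cm, "control", "perturbed")
de_d = nb_wald_contrast(cm, "control", "perturbed_drug")

fs = classify_flip(de_p, de_d, PERTURBATION_RULE, DRUG_RULE)
print(f"Flip(Up->Down): {len(fs.up_down)} of "
      f"{fs.n_perturbed('up_down')} up-DEGs "
      f"({round(flip_fraction(fs, 'up_down'))}%)")
print(f"Flip(Down->Up): {len(fs.down_up)} of "
      f"{fs.n_perturbed('down_up')} down-DEGs "
      f"({round(flip_fraction(fs, 'down_up'))}%)")

recovered = len(set(fs.up_down) & set(gt.genes_of("up_down")))
print(f"planted Flip(Up->Down) genes recovered: {recovered}/{len(gt.genes_of('up_down'))}")

scores = flip_score(de_p, de_d)
print("strongest flips:\n", scores.sort_values(ascending=False).head())

# flip_score is the per-gene reversal evidence (drug fold change opposing
# the perturbation); it feeds the TF-regulon ranking downstream.
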