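"""Resolving power: how many random ions identify a fly's diet, from
quantitative areas versus mere presence/absence?

The contrast dataset plants the diet signal purely in quantitative
levels (every ion is detectable in every sample), so the qualitative
per-sample profiles carry no diet information at all: quantitative
accuracy dominates at every batch size.
"""

import metaboflow as mf

table, _ = mf.simulate_quantitative_contrast(seed=1)
curve = mf.resolving_power_curves(
    table, batch_sizes=[10, 30, 100, 300, 1000], n_reps=200, seed=1
)

print("mean diet-classification accuracy over 200 random ion batches:")
print(f"{'batch size':>10} {'quantitative':>13} {'qualitative':>12}")
q = curve.for_mode("quantitative")
p = curve.for_mode("qualitative")
for (_, rq), (_, rp) in zip(q.iterrows(), p.iterrows()):
    print(f"{int(rq.batch_size):>10} {rq.mean_accuracy:>13.3f} {rp.mean_accuracy:>12.3f}")
print("\nAMI against the true diets at 300 ions: "
      f"quantitative {q.loc[q.batch_size == 300, 'mean_ami'].iloc[0]:.3f}, "
      f"qualitative {p.loc[p.batch_size == 300, 'mean_ami'].iloc[0]:.3f}")
# Accuracy ~1.0 from a few hundred quantitative ions, while presence
# profiles stay at the optimal-matching chance level (~0.4).
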