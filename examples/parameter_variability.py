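"""Does H depend on the spread of site strengths, or only on their mean?

Monte-Carlo draws of activation parameters compare each random vector's H
with the H of an all-equal surrogate at the same arithmetic mean.  For the
MWC model the two collapse when the mean activation is strong; the
independent model keeps a genuine dependence on the spread.  A companion
sweep counts how often H falls when one site is marginally weakened.
"""

from ultrasens import decreasing_proportion, mean_cv_experiment

df = mean_cv_experiment("mwc", [4], 1e-4, 0.9, count=200, seed=7, L=1000.0)
per_draw = df.drop_duplicates(["n", "draw"])
strong = per_draw[(per_draw["mean"] < 1e-2) & per_draw["defined"]]
gaps = (strong["H"] - strong["H_at_mean"]).abs()
print(f"MWC, n=4, {len(per_draw)} draws, {len(strong)} with mean c < 0.01:")
print(f"  median |H - H(mean)| = {gaps.median():.4f}, "
      f"95th percentile = {gaps.quantile(0.95):.4f}")
print("  -> with strong sites, H is set by the mean activation alone.\n")

prop = decreasing_proportion("mwc", [2, 6], [1000.0], count=300,
                             low=1e-4, high=0.9, seed=11)
for _, row in prop.iterrows():
    print(f"MWC n={int(row['n'])}, L=1000: H decreased when c1 grew in "
          f"{100 * row['proportion']:.1f}% of {int(row['defined_count'])} "
          f"defined draws")
print("\nStrengthening a site (smaller c) almost always raises H for many"
      "\nsites; with only two sites there are genuine exceptions.")
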