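"""Why batch-balanced folds matter: the best/average/worst-case spectrum.

On cohorts where the outcome label is confounded with batch, a simple
nearest-centroid classifier is scored across 3-fold partitions built three
ways: batch-balanced (best case), random (average case), and folds that
coincide with batch groups (worst case). Balanced folds give the classifier
a fair chance; batch-aligned folds force it to generalize to a technical
presentation it never saw.
"""

from cohortsplit.experiments import partition_spectrum

means = partition_spectrum(n_cohorts=10, seed=1)

print("mean cross-fold accuracy of the proxy classifier (10 cohorts):")
for strategy in ("best_case", "average_case", "worst_case"):
    print(f"  {strategy:13s} {means[strategy]:.3f}")

gap = means["average_case"] - means["worst_case"]
print(f"\nThe worst-case penalty ({gap:.3f} accuracy lost vs a random split)")
print("is what silently happens when a cohort's folds align with scanner,")
print("site or staining batch. Batch-balanced folds close the spread from")
print("the other side: every fold sees every technical presentation.")
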