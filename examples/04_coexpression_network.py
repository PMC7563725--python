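"""Build the weighted co-expression network and detect gene modules.

The soft-threshold power is the smallest one whose connectivity
distribution fits a scale-free law with R^2 > 0.85; adjacency becomes
topological overlap; modules are separated dendrogram branches of >= 30
genes; eigengene-correlated modules (r > 0.8) are merged; each module's
eigengene is correlated with the phenotype to find the key module.
"""

from coexfeat import default_spec, generate_expression
from coexfeat.network import (
    build_network, detect_modules, merge_modules, module_eigengenes,
    module_trait_correlation, scan_soft_thresholds, select_key_module,
    select_power,
)
from coexfeat.preprocess import correct_batch

matrix, truth = generate_expression(default_spec(seed=0))
corrected = correct_batch(matrix)

scan = scan_soft_thresholds(corrected)
print(scan.loc[scan["Power"].isin([1, 4, 8, 12]), :].round(3).to_string(index=False))
power = select_power(scan, r2_min=0.85)
print(f"\nselected power: {power:g} "
      f"(fit R^2 {scan.loc[scan['Power'] == power, 'SFT.R.sq'].iloc[0]:.3f})")

net = build_network(corrected, power)
labels = merge_modules(corrected, detect_modules(net.dissimilarity, min_size=30))
print("module sizes:", labels.value_counts().to_dict())

me, explained = module_eigengenes(corrected, labels)
trait = module_trait_correlation(me, corrected.phenotype)
print("\nmodule-trait correlations:")
print(trait.round(4).to_string())
key = select_key_module(trait, sizes=labels[labels != "grey"].value_counts())
print(f"\nkey module: {key}")
# The key module is the one whose summary profile (eigengene) tracks the
# cancer/normal status most strongly — the candidate disease module.
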