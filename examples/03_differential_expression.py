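"""Screen differentially expressed genes with the moderated t-test.

Gene-wise variances are shrunk toward a common prior before testing
(stabilising small-sample estimates), p-values are Benjamini-Hochberg
corrected, and genes pass with adj.p < 0.05 and |log2FC| > 1.
"""

from coexfeat import default_spec, generate_expression
from coexfeat.diffexpr import moderated_t_test, screen_de
from coexfeat.preprocess import correct_batch

matrix, truth = generate_expression(default_spec(seed=0))
corrected = correct_batch(matrix)

result = moderated_t_test(corrected)
hits = screen_de(result, alpha=0.05, lfc=1.0)

print(f"{len(hits)} significant genes "
      f"({hits.attrs['n_up']} up, {hits.attrs['n_down']} down in cancer)")
print("\nstrongest hits:")
print(hits.head(5).round(4).to_string())

strong_truth = {g for g, v in truth.de_genes.items() if abs(v) >= 1.5}
sens = len(set(hits.index) & strong_truth) / len(strong_truth)
print(f"\nsensitivity for planted |log2FC|>=1.5 genes: {sens:.1%}")
# logFC is cancer minus normal on the log2 scale, so positive = upregulated.
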