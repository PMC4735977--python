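"""Build a rank index over a synthetic cohort and classify planted pairs.

Simulates a latent-factor expression matrix (most probe pairs share a
common driver, as in a real compendium) with three planted pairs — linear,
rank-permuted (nonlinear), independent — builds the compressed all-pairs
index, and reports each planted pair's MI/|r| percentile ranks (RoMI, Ror).
"""

from coexpmi import CoexpressionIndex, pair_report, simulate_matrix

matrix = simulate_matrix(
    48, 400, kind="latent_factor",
    planted=("linear", "permuted_dependency", "independent"), seed=0,
)
index = CoexpressionIndex.build(matrix)
print(f"indexed {index.total_pairs} pairs "
      f"({matrix.n_probes} probes x {matrix.n_samples} samples)\n")

for stem in ("planted0_linear", "planted1_permuted_dependency", "planted2_independent"):
    rep = pair_report(matrix, f"{stem}_a", f"{stem}_b", index=index)
    print(f"{stem:30s} r = {rep.r:+.3f}  MI = {rep.mi:.3f}  "
          f"RoMI = {rep.ro_mi:2d}%  Ror = {rep.ro_r:2d}%")

print()
print("RoMI/Ror read: 'this percentage of all pairs score lower'.  The")
print("linear pair ranks high on both; the rank-permuted pair only on MI")
print("(its dependency is invisible to r); the independent pair on neither.")
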