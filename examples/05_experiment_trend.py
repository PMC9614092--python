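"""A small accuracy-versus-size experiment with the 95%-of-max summary.

Runs two reduction methods over a short size grid for the G+E model
under CV1 and prints the accuracy trend and the smallest size reaching
95% of the peak correlation (size_95) — the study's headline metric for
how much reduction each method tolerates.
"""

import sketchgs as sg

cfg = sg.SimConfig(n_lines=100, n_markers=2000, n_envs=3, block_size=80,
                   within_block_rho=0.8, n_causal=200, seed=13,
                   maf_range=(0.15, 0.5),
                   var_components=sg.TrueVariances(mu=8, var_E=1.0, var_g=1.0,
                                                   var_gE=0.0, var_eps=1.0))
geno = sg.simulate_genotypes(cfg)
pheno, _ = sg.simulate_phenotypes(geno, cfg)
X = sg.standardize(sg.clean_markers(geno)[0])

ec = sg.ExperimentConfig(
    size_grid=[100, 250, 500, 1000, X.n_markers],
    methods=("ran_proj", "cluster"),
    models=("GE",),
    schemes=("CV1",),
    n_dr_reps=5,
    n_cv_reps=3,
    master_seed=2,
    refit_per_fold=False,
    include_baseline=False,
)
out = sg.run_experiment(ec, X, pheno)

print(out.cells.pivot_table(index="size", columns="method",
                            values="mean_corr").round(3))
print()
for _, row in out.trends.iterrows():
    print(f"{row['method']:>8}: size_95 = {row['size_95']:>5} "
          f"(r = {row['corr_at_95']:.3f}, peak r = {row['max_corr']:.3f})")
# size_95 well below the full marker count reproduces the study's finding
# that a fraction of the markers suffices for near-peak accuracy.
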