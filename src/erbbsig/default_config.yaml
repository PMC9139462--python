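# Default run configuration for the erbbsig command-line interface.
seed: 0
output_dir: results
cell_lines: [MCF7]
noise_sd: 0.05
replicates: 3

# log10 parameter bounds for estimation
bounds_lower: -5.0
bounds_upper: 3.0

# multistart optimizer
n_starts: 3
maxiter: 200
ftol: 1.0e-9

# profile likelihood (chi-square 1-df 95% threshold)
profile_delta: 3.84
profile_max_steps: 100

# L1 regularization path
lambda_min: 0.01
lambda_max: 1000.0
n_lambda: 20

# parameters estimated by the `fit` subcommand (log10 scale)
fit_free_parameters:
  - act_cRAF_dimers
  - bas_MEK
  - phos_S6K_AKT
  - phos_S6K_ERK
  - k_cetuximab
  - dim_EE_EGF
  - deact_cRAF
  - dephos_ERK
  - bas_PI3K
  - phos_AKT_aPI3K
  - dephos_AKT
  - deg_D_EE
  - dim_23_NRG1
  - bas_cRAF
  - dephos_S6K

# fold-change candidates for the `l1-adapt` subcommand (one rate per
# quasi-equilibrated phosphorylation cycle plus dimer-layer turnover;
# mutually separable on the four-ligand panel)
l1_candidates:
  - deact_cRAF
  - dephos_MEK
  - dephos_ERK
  - dephos_S6K
  - dephos_AKT
  - deg_D_E2
  - deg_D_E3
  - deg_D_23

# ground-truth affine growth law for synthetic viability data
regression_truth:
  alpha1: -0.8
  beta1: 0.005
  beta2: 0.004
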