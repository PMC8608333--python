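[lattice]
size = 120
shell = "dist2"
copy_shell = "moore8"
perimeter = "edge"

[tumor]
total_cells = 120
fraction_h = 0.4
phenotype_mode = "single"
mu_h = 40.0
mu_h1 = 40.0
mu_h2 = 40.0
mu_mean = 40.0
mu_sigma = 0.0

[types]
[types.E]
T = 1.0
lambda_area = 1.0
target_area = 25.0

[types.H]
T = 1.0
lambda_area = 1.0
target_area = 25.0
lambda_perim = 0.0
target_perim = 0.0

[contact]
J_EE = 2.0
J_HH = 6.0
gamma_Em = 19.0
gamma_Hm = 3.0

[motility]
tau = 50
mode = "com"

[run]
mcs = 10000
record_every = 2000
replicates = 3
seed = 0

[sweep]
gamma = [1, 2, 3, 4]
mu = [20, 30, 40, 50]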