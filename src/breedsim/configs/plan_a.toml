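# Plan A: 25-year line-breeding program with phenotypic selection.
# Full-scale cohort sizes; founder LD is simulated (imported phased genomes
# may be substituted through the API).
name = "plan_a"
n_replicates = 60

[genome]
n_chromosomes = 21
chrom_length = 1.5
n_loci = 9582
n_qtl_random = 1039
n_ibd = 10

[founder]
n_pat = 50
n_mat = 50
ng_founder = 100
mutation_rate = 0.0025
culling_fraction = 0.05

[traits]
names = ["BVP", "YP", "YA"]
sigma_g2 = [1.0, 1.0, 1.0]
correlations = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.3], [0.0, 0.3, 1.0]]

[traits.noise.BVP]
h2 = 0.1
[traits.noise.YP]
h2_plot = 0.2
ns = 20
homozygosity = 0.9375
[traits.noise.YA]
h2_plot = 0.3
ns = 100
homozygosity = 0.96875

[plan]
last_generation = 8
horizon = 25
calendar = [0, 1, 2, 3, 4, 5, 6, 7]

[plan.crossing]
n_crosses = 50
max_uses = 5
n_seeds_per_cross = 1

[plan.parent_source]
n_parents = 20
founder_cycles = 7
store_generations = [5, 6, 7]
policy = "uniform"
base_inbred = true

[[plan.stages]]
generation = 1
propagation = {type = "selfing", n_seeds = 10, per = "plant"}

[[plan.stages]]
generation = 2
phenotyping = [{trait = "BVP", level = "plant"}]
selection = {unit = "within_family", family = "f1", criterion = "phenotype", trait = "BVP", n_selected = 5}
propagation = {type = "selfing", n_seeds = 30, per = "plant"}

[[plan.stages]]
generation = 3
phenotyping = [{trait = "YP", level = "family", family = "f1", n_plots = 3}]
selection = {unit = "entire_family", family = "f1", criterion = "phenotype", trait = "YP", n_selected = 45}
propagation = {type = "selfing", n_seeds = 60, per = "family"}

[[plan.stages]]
generation = 4
phenotyping = [{trait = "BVP", level = "plant"}]
selection = {unit = "within_family", family = "f1", criterion = "phenotype", trait = "BVP", n_selected = 5}
propagation = {type = "selfing", n_seeds = 20, per = "plant"}
start_lines = true

[[plan.stages]]
generation = 5
phenotyping = [{trait = "YP", level = "family", family = "line", n_plots = 1}]
selection = {unit = "entire_family", family = "line", criterion = "phenotype", trait = "YP", n_selected = 75}
propagation = {type = "selfing", n_seeds = 900, per = "family"}
store_germplasm = true

[[plan.stages]]
generation = 6
phenotyping = [{trait = "YA", level = "family", family = "line", n_plots = 9}]
selection = {unit = "entire_family", family = "line", criterion = "phenotype", trait = "YA", n_selected = 30}
propagation = {type = "selfing", n_seeds = 900, per = "family"}
store_germplasm = true

[[plan.stages]]
generation = 7
phenotyping = [{trait = "YA", level = "family", family = "line", n_plots = 9}]
selection = {unit = "entire_family", family = "line", criterion = "phenotype", trait = "YA", n_selected = 5}
propagation = {type = "selfing", n_seeds = 900, per = "family"}
store_germplasm = true
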