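# Plan C (speed breeding + genomic selection) at reduced test scale: 1 chromosome, 500 loci (every 10th a QTL),
# cohort sizes divided by 5, simulated Fisher-Wright founder population.
name = "plan_c_small"
n_replicates = 10

[genome]
n_chromosomes = 1
chrom_length = 3.0
n_loci = 500
qtl_every_n = 10
n_ibd = 20

[founder]
n_pat = 25
n_mat = 25
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
ns = 4
homozygosity = 0.9375
[traits.noise.YA]
h2_plot = 0.3
ns = 20
homozygosity = 0.96875

[plan]
last_generation = 8
horizon = 25
calendar = [0, 0, 0, 0, 1, 2, 3, 4]
burn_in_switch = 11

[plan.crossing]
n_crosses = 10
max_uses = 4
n_seeds_per_cross = 1

[plan.parent_source]
n_parents = 10
founder_cycles = 5
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
propagation = {type = "selfing", n_seeds = 6, per = "plant"}

[[plan.stages]]
generation = 3
phenotyping = [{trait = "YP", level = "family", family = "f1", n_plots = 3}]
selection = {unit = "entire_family", family = "f1", criterion = "phenotype", trait = "YP", n_selected = 9}
propagation = {type = "selfing", n_seeds = 12, per = "family"}

[[plan.stages]]
generation = 4
phenotyping = [{trait = "BVP", level = "plant"}]
selection = {unit = "within_family", family = "f1", criterion = "phenotype", trait = "BVP", n_selected = 5}
propagation = {type = "selfing", n_seeds = 4, per = "plant"}
start_lines = true
genotype = true

[[plan.stages]]
generation = 5
phenotyping = [{trait = "YP", level = "family", family = "line", n_plots = 1}]
selection = {unit = "entire_family", family = "line", criterion = "gblup", burn_in_criterion = "phenotype", trait = "YP", index_trait = "YA", n_selected = 15}
propagation = {type = "selfing", n_seeds = 180, per = "family"}
store_germplasm = true

[[plan.stages]]
generation = 6
phenotyping = [{trait = "YA", level = "family", family = "line", n_plots = 9}]
selection = {unit = "entire_family", family = "line", criterion = "gblup", burn_in_criterion = "phenotype", trait = "YA", index_trait = "YA", n_selected = 6}
propagation = {type = "selfing", n_seeds = 180, per = "family"}
store_germplasm = true

[[plan.stages]]
generation = 7
phenotyping = [{trait = "YA", level = "family", family = "line", n_plots = 9}]
selection = {unit = "entire_family", family = "line", criterion = "gblup", burn_in_criterion = "phenotype", trait = "YA", index_trait = "YA", n_selected = 1}
propagation = {type = "selfing", n_seeds = 180, per = "family"}
store_germplasm = true
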