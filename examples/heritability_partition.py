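"""Broad- and narrow-sense heritability of fitness and adaptability.

Broad-sense H² asks how much of the observed variance is founder genotype
rather than noise; narrow-sense h² (REML on a kinship matrix) asks how much
an additive model of the loci could ever explain.  The gap between the two
is the footprint of epistasis.
"""

import evoherit as ev
from evoherit.pipeline import founder_summaries, population_increments

ds = ev.simulate_dataset(ev.default_config(seed=1))
fsum = founder_summaries(ds.fitness_table, ds.genotypes.founders)
incr = population_increments(ds.fitness_table, ds.populations.table, fsum)

# founder fitness at OT: total variance vs measurement error
sub = fsum[fsum["environment"] == "OT"].set_index("founder_id")
sub = sub.loc[ds.genotypes.founders]
vc = ev.broad_sense_fitness(sub["mean"], sub["error_var"])
print(f"fitness OT:  sigma_t² = {vc.sigma_t2:.2e}, "
      f"sigma_eps² = {vc.sigma_noise2:.2e}, H² = {vc.H2:.3f}")
# H² near 1: measurement error is tiny relative to genetic differences.

# adaptability at OT: within-founder spread (evolutionary stochasticity +
# error) vs between-founder differences
home = incr[(incr["role"] == "home") & (incr["evolved_env"] == "OT")]
groups = {f: g["increment"].to_numpy() for f, g in home.groupby("founder_id")}
vc_d = ev.broad_sense_increment(groups)
print(f"adaptability OT:  H² = {vc_d.H2:.3f} "
      f"(founders differ systematically in how fast they adapt)")

# narrow-sense h² by REML on the genomic relationship matrix
kin = ev.kinship_matrix(ds.genotypes)
reml = ev.narrow_sense_reml(sub["mean"].to_numpy(), kin)
print(f"fitness OT:  h² = {reml.h2:.3f} "
      f"(sigma_a² = {reml.sigma_a2:.2e}, sigma_e² = {reml.sigma_e2:.2e})")
print("the H² − h² gap is variance an additive locus model cannot reach")
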