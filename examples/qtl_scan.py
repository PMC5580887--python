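"""Iterative forward QTL scan with permutation significance.

Each iteration residualizes the trait on the QTLs found so far, scores
every locus by LOD = −(n/2)·log10(1 − r²), and keeps the genome-wide peak
if it beats a permutation null at alpha = 0.05.
"""

import evoherit as ev
from evoherit.pipeline import founder_summaries

ds = ev.simulate_dataset(ev.default_config(seed=1))
fsum = founder_summaries(ds.fitness_table, ds.genotypes.founders)
trait = fsum[fsum["environment"] == "HT"].set_index("founder_id")["mean"]
trait = trait.loc[ds.genotypes.founders]

hits = ev.forward_scan(ds.genotypes, trait.to_numpy(), n_perm=500, seed=2)
print(f"{len(hits)} QTLs for founder fitness at HT "
      f"(true layout: 6 planted loci, largest on chr14):")
for h in hits:
    print(f"  {h.chrom}:{h.pos}  LOD = {h.lod:6.1f}  p = {h.p_value:.4f}  "
          f"CI = [{h.ci_lo}, {h.ci_hi}]  effect = {h.effect:+.3f}")
# 'effect' is the fitted additive difference between the BY and RM alleles;
# the largest hit should recover the planted +0.19 focal-locus effect.

r2 = ev.additive_model_r2(ds.genotypes, [h.locus for h in hits],
                          trait.to_numpy())
print(f"variance explained by the additive QTL model: r² = {r2:.3f}")
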