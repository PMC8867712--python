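"""Genotype QC, shared-polymorphism accounting, kinship and structure.

Filters low-call-rate samples, classifies loci per species (CR<80 /
monomorphic / polymorphic, with shared counts), estimates centred-IBS
kinship and tests its skewness - the half-sib signature.
"""

import markertrait as mt

cfg = mt.SimConfig(seed=2, n_species=3, pops_per_species=3,
                   families_per_pop=4, offspring_per_family=8, n_loci=1500,
                   lowcall_sample_rate=0.05)
g, pheno, _ = mt.simulate_trial(cfg)

filtered, removed = mt.filter_samples_by_call_rate(g, 0.80)
print(f"removed {len(removed)} samples with call rate < 80%")

subsets = {sp: list(filtered.sample_meta.index[filtered.sample_meta["species"] == sp])
           for sp in filtered.sample_meta["species"].unique()}
_, counts = mt.locus_class_by_species(filtered, subsets)
print("\nLocus classes per species and shared among species:")
print(counts)

K = mt.centered_ibs_kinship(filtered)
z, p = mt.dagostino_skewness(K.offdiagonal())
print(f"\nkinship skewness z = {z:.1f}, p = {p:.2e} "
      "(positive: half-sib pairs create a heavy right tail)")

pcs = mt.pca_covariates(filtered, 3)
print("top-3 PC eigenvalues:", pcs.eigenvalues.round(2),
      "(PC1 separates the species)")
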