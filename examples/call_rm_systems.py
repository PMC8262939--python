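"""Call complete RM systems from annotation evidence tables.

Builds a synthetic evidence set (proteins with coordinates, profile hits,
alignment hits) containing planted RM systems and rule-boundary decoys,
runs the genomic-context calling rules, and compares the per-genome counts
with the planted truth.
"""

from rmeco.annotation import annotate_genomes
from rmeco.synth import AnnotationFixtureConfig, gen_annotation_fixture

cfg = AnnotationFixtureConfig(seed=11, n_genomes=5, n_paired=3, n_fused=1,
                              n_putative_iig=2, n_decoys=7)
proteins, domhits, alihits, truth = gen_annotation_fixture(cfg)

print(f"{len(proteins)} proteins, {len(domhits)} domain hits, "
      f"{len(alihits)} alignment hits across {cfg.n_genomes} genomes\n")

counts = annotate_genomes(proteins, domhits, alihits).reset_index()
merged = counts.merge(truth, on="genome_id", suffixes=("", "_truth"))

print(merged[["genome_id", "n_paired", "n_fused", "n_putative_iig",
              "rm_total", "rm_total_truth", "rm_total_no_iig"]].to_string(index=False))

exact = (merged["rm_total"] == merged["rm_total_truth"]).all()
print(
    f"\nexact recovery of planted counts: {exact}"
    "\nEach genome contains decoys that each break exactly one rule"
    "\n(pair gap 4,001 bp, alignment at 74% coverage or E=1.1e-5, a 750-aa"
    "\nmethyltransferase, ResIII with a false-positive covariate); none of"
    "\nthem is counted.  rm_total_no_iig drops the >750-aa size-based type"
    "\nIIG candidates."
)
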