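"""Simulate the synthetic cohort: genotypes, variants, phenotype replicates.

Writes variants.tsv, genotypes.tsv, phenotypes.tsv and ground_truth.json into
results/pipeline and reports the realized cohort characteristics (variant
count, rare fraction, affected fraction).
"""

import pandas as pd

from _config import CONFIG, PIPELINE_DIR
from bndissect.pipeline import stage_simulate

if __name__ == "__main__":
    info = stage_simulate(CONFIG, PIPELINE_DIR)
    variants = pd.read_csv(PIPELINE_DIR / "variants.tsv", sep="\t")
    phen = pd.read_csv(PIPELINE_DIR / "phenotypes.tsv", sep="\t")
    n_reps = phen["replicate"].nunique()
    print(f"wrote cohort to {PIPELINE_DIR}")
    print(f"  {len(variants)} variants in {variants['gene_id'].nunique()} genes; "
          f"{(variants['maf'] < 0.01).mean():.0%} with MAF < 1%; "
          f"{(variants['annotation'] == 'nonsynonymous').mean():.0%} nonsynonymous")
    print(f"  {n_reps} phenotype replicates; affected fraction "
          f"{phen['affected'].mean():.3f} (target {CONFIG.generator.prevalence})")
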