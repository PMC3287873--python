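"""Shared configuration of the main analysis run.

A desk-scale analog of the emulated workshop design: 697 individuals, 120
genes (10 causal for Q1, 8 for Q2, all acting through nonsynonymous burden),
20 phenotype replicates sharing one genotype matrix.  The panel is kept wide
enough that the two-group mixture behind the annotation weight w has genes to
work with.  All scripts write into ``results/pipeline`` so each stage can
pick up the previous stage's artifacts.
"""

from pathlib import Path

from bndissect.bayesnet import McmcConfig
from bndissect.pipeline import PipelineConfig
from bndissect.synthetic_data import GeneratorConfig, default_gene_ids

RESULTS = Path(__file__).resolve().parent.parent / "results"
PIPELINE_DIR = RESULTS / "pipeline"

_IDS = default_gene_ids(120)

CONFIG = PipelineConfig(
    generator=GeneratorConfig(
        n_genes=120,
        causal_genes={"Q1": tuple(_IDS[:10]), "Q2": tuple(_IDS[10:18])},
        effect_size=0.6,
        n_replicates=20,
        seed=0,
    ),
    mcmc=McmcConfig(iterations=4_000),
    master_seed=2026,
)
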