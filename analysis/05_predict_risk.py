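"""Network-guided disease risk prediction on held-out replicates.

Trains an SVM on half the replicates using the environment variables plus the
QTL genes selected by the consensus network, and averages AUC over the other
half.
"""

from _config import CONFIG, PIPELINE_DIR
from bndissect.pipeline import stage_predict

if __name__ == "__main__":
    rep = stage_predict(CONFIG, PIPELINE_DIR)
    print(f"risk prediction ({rep['model']}, features: {rep['features']})")
    print(f"  QTL genes used: {len(rep['qtl_genes'])}")
    print(f"  held-out AUC = {rep['mean_auc']:.3f} +- {rep['sd_auc']:.3f} over "
          f"{len(rep['test_replicates'])} replicates")
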