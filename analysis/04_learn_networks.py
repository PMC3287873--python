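"""Learn one Bayesian network per replicate and build the consensus.

Each replicate's chain proposes add/delete/reverse moves under the role
constraints and keeps its best BIC structure; edges are counted across
replicates and thresholded into the final network (written as GraphML and
DOT with the per-edge confidence counts).  Reports recovered ground-truth
edges.
"""

import pandas as pd

from _config import CONFIG, PIPELINE_DIR
from bndissect.io import read_ground_truth
from bndissect.pipeline import stage_learn_consensus

if __name__ == "__main__":
    info = stage_learn_consensus(CONFIG, PIPELINE_DIR)
    truth = read_ground_truth(PIPELINE_DIR / "ground_truth.json")
    edges = pd.read_csv(PIPELINE_DIR / "edge_confidence.tsv", sep="\t")
    kept = edges[edges["retained"]]
    found = {(r["source"], r["target"]) for _, r in kept.iterrows()}
    true_set = set(map(tuple, truth.true_edges))
    # only ground-truth edges whose endpoints are both in the learned node set
    nodes = set(info["selected"]) | {"age", "sex", "smoking", "Q1", "Q2", "Q4", "affected"}
    reachable_truth = {e for e in true_set if e[0] in nodes and e[1] in nodes}
    print(f"consensus over {CONFIG.generator.n_replicates} replicates, "
          f"cutoff {info['cutoff']}: {info['n_edges']} edges kept")
    print(f"  ground-truth edges recovered: {len(found & reachable_truth)}"
          f"/{len(reachable_truth)} (among representable ones)")
    print(f"  extra edges: {len(found - true_set)}")
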