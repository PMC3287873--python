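"""Plain-text readers and writers for every pipeline artifact.

Everything is tab-separated or JSON so intermediate results stay inspectable:
variant table, genotype matrix, phenotype replicates (stacked with a
``replicate`` column), gene-score matrices (with a provenance header comment),
screen results, edge-confidence tables, plus a minimal VCF writer and an
optional cyvcf2-based VCF reader for external genotype data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import EdgeConfidenceTable
from .errors import DataError
from .gene_scores import GeneScoreMatrix
from .screening import ScreenResult
from .synthetic_data import GroundTruth, ReplicateSet

__all__ = [
    "write_variant_table",
    "read_variant_table",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_phenotypes",
    "read_phenotypes",
    "write_ground_truth",
    "read_ground_truth",
    "write_gene_scores",
    "read_gene_scores",
    "write_screen_result",
    "write_edge_table",
    "read_edge_table",
    "write_vcf",
    "read_vcf",
]


def write_variant_table(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene_id", "maf", "annotation"}
    if not required <= set(df.columns):
        raise DataError(f"variant table missing columns: {sorted(required - set(df.columns))}")
    return df


def write_genotype_matrix(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="individual_id")


def read_genotype_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual_id")


def write_phenotypes(phenotypes: Sequence[pd.DataFrame], path) -> None:
    """All replicates stacked with ``replicate`` and ``individual_id`` columns."""
    frames = []
    for r, ph in enumerate(phenotypes):
        f = ph.copy()
        f.insert(0, "individual_id", ph.index)
        f.insert(0, "replicate", r)
        frames.append(f)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> list[pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, grp in df.groupby("replicate", sort=True):
        g = grp.set_index("individual_id").drop(columns=["replicate"])
        g.index.name = None
        out.append(g)
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "causal_genes": {t: list(g) for t, g in truth.causal_genes.items()},
        "true_edges": [list(e) for e in truth.true_edges],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        causal_genes={t: tuple(g) for t, g in payload["causal_genes"].items()},
        true_edges=tuple(tuple(e) for e in payload["true_edges"]),
    )


def write_gene_scores(matrix: GeneScoreMatrix, path) -> None:
    header = (
        f"# score_kind={matrix.score_kind}\tweight_fn={matrix.weight_fn}"
        f"\tw={'' if matrix.weight is None else matrix.weight}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        matrix.data.to_csv(fh, sep="\t", index_label="individual_id")


def read_gene_scores(path) -> GeneScoreMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DataError("gene score file is missing its provenance header")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
        )
        data = pd.read_csv(fh, sep="\t", index_col="individual_id")
    w = meta.get("w", "")
    return GeneScoreMatrix(
        data=data,
        score_kind=meta.get("score_kind", "unknown"),
        variant_counts=pd.Series(dtype=int),
        degenerate_genes=frozenset(),
        weight_fn=meta.get("weight_fn", "unknown"),
        weight=float(w) if w else None,
    )


def write_screen_result(result: ScreenResult, tsv_path, json_path=None) -> None:
    counts = result.retention_counts
    retained = result.retained
    df = pd.DataFrame(
        {
            "gene": counts.index,
            "response": result.response,
            "retention_count": counts.to_numpy(),
            "retained": [g in retained for g in counts.index],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "response": result.response,
            "mode": result.mode,
            "p_cutoff": result.p_cutoff,
            "retention_threshold": result.retention_threshold,
            "n_replicates": result.n_replicates,
            "retained": sorted(retained),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def write_edge_table(table: EdgeConfidenceTable, path, cutoff: int | None = None) -> None:
    df = table.counts.copy()
    if cutoff is not None:
        df["retained"] = df["count"] >= cutoff
    df.to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(variants: pd.DataFrame, genotypes: pd.DataFrame, path) -> None:
    """Minimal uncompressed VCF 4.2 with the annotation in the INFO/ANN field."""
    inds = list(genotypes.index)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Functional annotation">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds) + "\n")
        G = genotypes.to_numpy()
        for j, row in enumerate(variants.itertuples(index=False)):
            info = f"ANN={row.annotation};GENE={row.gene_id};MAF={row.maf:.6g}"
            gts = "\t".join(gt_codes[int(g)] for g in G[:, j])
            fh.write(f"1\t{j + 1}\t{row.variant_id}\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF written by :func:`write_vcf` (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise DataError("reading VCF requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    rows, columns = [], []
    for rec in vcf:
        rows.append(
            {
                "variant_id": rec.ID,
                "gene_id": rec.INFO.get("GENE"),
                "maf": float(rec.INFO.get("MAF")),
                "annotation": rec.INFO.get("ANN"),
            }
        )
        columns.append(np.array([sum(gt[:2]) for gt in rec.genotypes], dtype=np.int8))
    variants = pd.DataFrame(rows)
    genotypes = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(inds), 0)),
        index=inds,
        columns=variants["variant_id"].tolist() if rows else [],
    )
    return variants, genotypes


def replicate_set_to_dir(rs: ReplicateSet, out_dir) -> dict[str, str]:
    """Write a full replicate set into a directory; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "variants": str(out / "variants.tsv"),
        "genotypes": str(out / "genotypes.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "truth": str(out / "ground_truth.json"),
    }
    write_variant_table(rs.variants, files["variants"])
    write_genotype_matrix(rs.genotypes, files["genotypes"])
    write_phenotypes(rs.phenotypes, files["phenotypes"])
    write_ground_truth(rs.truth, files["truth"])
    return files
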