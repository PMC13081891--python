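"""Delimited-text formats used by the command-line pipeline.

All tables are TSV with a header row and the sample identifier in the
first column (samples x features).  Phenotype tables carry a leading
``#type`` line tagging each column as continuous / binary / count.  LD
blocks use BED conventions (0-based, half-open intervals).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .simulate import PhenotypeTable, SyntheticStudy

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_phenotypes",
    "read_phenotypes",
    "write_blocks",
    "read_blocks",
    "write_gene_map",
    "read_gene_map",
    "write_study",
    "config_digest",
    "write_manifest",
]

_TYPES = {"continuous", "binary", "count"}


def write_matrix(values, columns, path, sample_ids=None, index_name="sample_id"):
    """Samples x features TSV with sample IDs in the first column."""
    n = np.asarray(values).shape[0]
    idx = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame(np.asarray(values), columns=list(columns), index=idx)
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as err:
        raise FormatError(f"{path}: malformed matrix TSV ({err})") from err
    return df


def write_phenotypes(phenotypes: PhenotypeTable, path, sample_ids=None):
    n = phenotypes.values.shape[0]
    idx = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("#type\t" + "\t".join(phenotypes.types) + "\n")
        df = pd.DataFrame(phenotypes.values, columns=phenotypes.ids, index=idx)
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t")


def read_phenotypes(path) -> PhenotypeTable:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#type"):
            raise FormatError(f"{path}: line 1: expected a '#type' tag line")
        types = first.split("\t")[1:]
        bad = set(types) - _TYPES
        if bad:
            raise FormatError(f"{path}: line 1: unknown phenotype types {sorted(bad)}")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if len(types) != df.shape[1]:
        raise FormatError(f"{path}: {len(types)} type tags for {df.shape[1]} phenotype columns")
    return PhenotypeTable(values=df.to_numpy(dtype=float), types=types, ids=list(df.columns))


def write_blocks(blocks: pd.DataFrame, path):
    """BED file: chrom, start, end, block_id (tab-separated, no header)."""
    blocks[["chrom", "start", "end", "block_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_blocks(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "block_id"],
            dtype={"chrom": str, "start": int, "end": int, "block_id": str},
        )
    except (ValueError, pd.errors.ParserError) as err:
        raise FormatError(f"{path}: malformed BED block file ({err})") from err
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: block end must exceed start (half-open intervals)")
    return df


def write_gene_map(gene_map: pd.DataFrame, path):
    gene_map[["gene", "region", "snps"]].to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "region", "snps"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: line 1: missing column(s) {sorted(missing)}")
    return df


def write_study(study: SyntheticStudy, out_dir):
    """Write a synthetic study as the TSV bundle the CLI pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(study.ref_genotypes.values, study.ref_genotypes.snp_ids, out / "ref_genotypes.tsv")
    write_matrix(study.gwas_genotypes.values, study.gwas_genotypes.snp_ids, out / "gwas_genotypes.tsv")
    write_matrix(study.ref_expression, study.gene_ids, out / "ref_expression.tsv")
    write_phenotypes(study.phenotypes, out / "phenotypes.tsv")
    write_gene_map(study.gene_map, out / "gene_map.tsv")
    truth = study.truth
    sidecar = {
        "causal_sets": [sorted(int(j) for j in s) for s in truth.causal_sets],
        "true_B": truth.true_B.tolist(),
        "true_Lambda": truth.true_Lambda.tolist(),
        "true_gamma": [g.tolist() for g in truth.true_gamma],
        "tau2": truth.tau2.tolist(),
        "scenario": study.config.scenario,
        "gene_ids": study.gene_ids,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh)
    return out


def config_digest(obj) -> str:
    """Stable short hash of a configuration mapping (for run manifests)."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path, config: dict, seed, extra=None):
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_digest(config),
        "seed": seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
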