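"""Readers and writers binding the pipeline stages.

Conventions: BED input is 0-based half-open and is converted to the
1-based inclusive coordinates used internally (start+1, end); strand is
ignored since derived-allele frequencies are strand-free after
polarization.  Every output file carries a comment header with the
package version, the seed and a parameter digest.  Logging goes to
stderr; results only to files or stdout.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import header_lines
from .demography import DemographicModel, JointSFS
from .freqs import GenotypeLikelihoodMatrix, SITE_COLUMNS
from .pbs import GeneAnnotation

__all__ = [
    "write_frame",
    "read_frame",
    "read_genes_bed",
    "write_genes_bed",
    "read_model_json",
    "write_model_json",
    "read_sfs_tsv",
    "write_sfs_tsv",
    "read_gl_tsv",
    "write_gl_tsv",
    "read_gl_vcf",
    "file_checksum",
    "write_manifest",
]


def write_frame(df: pd.DataFrame, path, seed=None, params=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- genes (BED) ------------------------------------------------------

def read_genes_bed(path, flank: int = 10_000) -> list[GeneAnnotation]:
    """BED (0-based half-open) -> 1-based inclusive gene annotations."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: need at least chrom, start, end")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"gene{ln}"
            genes.append(GeneAnnotation(gene_id=name, chrom=chrom,
                                        start=start + 1, end=end, flank=flank))
    return genes


def write_genes_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# -- demographic model (JSON) ----------------------------------------

def write_model_json(model: DemographicModel, path) -> None:
    d = model.to_dict()
    for p in d["populations"]:
        for e in p["epochs"]:
            if e["end_gen"] == math.inf:
                e["end_gen"] = "inf"
    Path(path).write_text(json.dumps(d, indent=2))


def read_model_json(path) -> DemographicModel:
    d = json.loads(Path(path).read_text())
    for p in d["populations"]:
        for e in p["epochs"]:
            if e["end_gen"] == "inf":
                e["end_gen"] = math.inf
    return DemographicModel.from_dict(d)


# -- joint SFS (TSV, one row per occupied cell) ----------------------

def write_sfs_tsv(sfs: JointSFS, path, seed=None) -> None:
    df = sfs.to_frame()
    with open(path, "w") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write("# pops=" + ",".join(sfs.pops) + "\n")
        fh.write("# shape=" + ",".join(str(s) for s in sfs.counts.shape) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_sfs_tsv(path) -> JointSFS:
    pops = shape = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# pops="):
                pops = line.strip().split("=", 1)[1].split(",")
            if line.startswith("# shape="):
                shape = [int(x) for x in line.strip().split("=", 1)[1].split(",")]
    if pops is None or shape is None:
        raise ValueError(f"{path}: missing '# pops=' / '# shape=' header lines")
    df = pd.read_csv(path, sep="\t", comment="#")
    return JointSFS.from_frame(df, pops, shape)


# -- genotype likelihoods --------------------------------------------

def write_gl_tsv(glm: GenotypeLikelihoodMatrix, path, seed=None) -> None:
    """Long format: one row per (site, individual) with GL0..GL2."""
    S, I = glm.n_sites, glm.n_individuals
    sites = glm.sites[SITE_COLUMNS]
    rec = sites.loc[sites.index.repeat(I)].reset_index(drop=True)
    rec["individual"] = np.tile(np.arange(I), S)
    for g in range(3):
        rec[f"GL{g}"] = glm.gl[:, :, g].ravel()
    rec["missing"] = glm.missing.ravel().astype(int)
    write_frame(rec, path, seed=seed)


def read_gl_tsv(path) -> GenotypeLikelihoodMatrix:
    df = read_frame(path)
    sites = df[SITE_COLUMNS].drop_duplicates().reset_index(drop=True)
    inds = np.sort(df["individual"].unique())
    S, I = len(sites), len(inds)
    key = sites.set_index(["chrom", "pos"]).index
    site_ix = pd.Series(np.arange(S), index=key)
    rows = site_ix.loc[list(zip(df["chrom"], df["pos"]))].to_numpy()
    cols = pd.Series(np.arange(I), index=inds).loc[df["individual"]].to_numpy()
    gl = np.zeros((S, I, 3))
    missing = np.zeros((S, I), dtype=bool)
    for g in range(3):
        gl[rows, cols, g] = df[f"GL{g}"].to_numpy()
    if "missing" in df:
        missing[rows, cols] = df["missing"].to_numpy().astype(bool)
    return GenotypeLikelihoodMatrix(sites, gl, missing)


def read_gl_vcf(path, ancestral_tag: str = "AA") -> GenotypeLikelihoodMatrix:
    """Minimal VCF reader: biallelic SNPs with a PL or GL FORMAT field.

    Derived polarization uses the ancestral-allele INFO tag: when the
    ancestral allele equals ALT, the likelihood triple is reversed so
    index 2 always means homozygous derived.  Sites without the tag are
    polarized REF=ancestral.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, gls, miss = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        anc = var.INFO.get(ancestral_tag) or var.REF
        if anc not in (var.REF, var.ALT[0]):
            continue
        flip = anc == var.ALT[0]
        pl = var.format("PL")
        if pl is not None:
            pl = np.asarray(pl, float)
            missing = np.all(pl < 0, axis=1) | np.isnan(pl).any(axis=1)
            pl = np.where(pl < 0, 0, pl)
            gl = np.power(10.0, -np.minimum(pl, 300) / 10.0)
        else:
            g = var.format("GL")
            if g is None:
                continue
            g = np.asarray(g, float)
            missing = np.isnan(g).any(axis=1)
            gl = np.power(10.0, np.nan_to_num(g))
        if flip:
            gl = gl[:, ::-1]
            der, anc_allele = var.REF, var.ALT[0]
        else:
            der, anc_allele = var.ALT[0], var.REF
        m = gl.max(axis=1, keepdims=True)
        gl = np.divide(gl, m, out=np.zeros_like(gl), where=m > 0)
        gl[missing] = [1.0, 0.0, 0.0]
        rows.append({"chrom": var.CHROM, "pos": var.POS,
                     "ancestral": anc_allele, "derived": der})
        gls.append(gl)
        miss.append(missing)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic sites with PL/GL")
    sites = pd.DataFrame(rows)
    return GenotypeLikelihoodMatrix(sites, np.stack(gls), np.stack(miss))


# -- manifest ---------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, stage: str, inputs: dict, outputs: dict,
                   params: dict, seed) -> dict:
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": {k: str(v) for k, v in params.items()},
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: {"path": str(v), "sha256": file_checksum(v)}
                    for k, v in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
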