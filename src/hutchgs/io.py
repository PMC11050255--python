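"""Readers and writers for the on-disk formats.

Genotypes travel as VCF v4.2 (GT from rounded dosages plus a DS dosage
FORMAT field; DS is preferred on read) or as a plain TSV dosage table
(markers as rows).  Phenotypes, true values and GEBVs are TSV; the GRM is
written either as an id-labelled dense TSV or as a compact binary triple
(`<stem>.ids` text file plus `<stem>.bin` float64 lower triangle, row-major);
variance components are JSON.  Every writer has a matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GRM
from .mixedmodel import VarCompMV, VarCompUV
from .simulate import GenotypeMatrix, TrueValues


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """VCF v4.2 with GT (rounded dosage) and DS (expected dosage) fields.
    Alleles are written as generic A/B REF/ALT; dosage counts the ALT allele."""
    path = Path(path)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hutchgs\n")
        for chrom in pd.unique(genotypes.chromosome):
            length = int(genotypes.position[genotypes.chromosome == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for j in range(genotypes.n_markers):
            ds = genotypes.dosage[:, j]
            fields = [
                f"{gt_codes[int(round(min(max(d, 0), 2)))]}:{d:g}" for d in ds
            ]
            fh.write(f"{genotypes.chromosome[j]}\t{genotypes.position[j]}\t"
                     f"{genotypes.marker_ids[j]}\tA\tB\t.\tPASS\t.\tGT:DS\t"
                     + "\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a VCF: the DS FORMAT field when present, otherwise
    the ALT-allele count from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ds = None
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            ds = None
        if ds is None or np.all(np.isnan(ds)):
            ds = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
            ds[ds == 3] = 2.0
        rows.append(ds)
    vcf.close()
    dosage = np.array(rows).T
    return GenotypeMatrix(sample_ids=samples, marker_ids=marker_ids,
                          chromosome=np.array(chroms), position=np.array(positions),
                          dosage=dosage)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Markers as rows: marker_id, chromosome, position, then one dosage
    column per sample."""
    df = pd.DataFrame(genotypes.dosage.T,
                      columns=genotypes.sample_ids)
    df.insert(0, "position", genotypes.position)
    df.insert(0, "chromosome", genotypes.chromosome)
    df.insert(0, "marker_id", genotypes.marker_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["marker_id", "chromosome", "position"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        sample_ids=samples,
        marker_ids=[str(m) for m in df["marker_id"]],
        chromosome=df["chromosome"].to_numpy(),
        position=df["position"].to_numpy(),
        dosage=df[samples].to_numpy(dtype=float).T,
    )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf/.vcf.gz -> VCF, anything else -> dosage TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_tsv(path)


# ---------------------------------------------------------------------------
# phenotypes and true values
# ---------------------------------------------------------------------------

def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["id"] = df["id"].astype(str)
    return df


def write_true_values(truth: TrueValues, path: str | Path) -> None:
    df = pd.DataFrame(truth.true_breeding_values, columns=truth.trait_names)
    df.insert(0, "id", truth.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_true_values(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qtl_effects(truth: TrueValues, path: str | Path) -> None:
    df = pd.DataFrame(truth.qtl_effects, columns=truth.trait_names)
    df.insert(0, "qtl_id", truth.qtl_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    """Dense id-labelled matrix with a one-line header carrying the scaling
    metadata as a comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#scaling_constant={grm.scaling_constant!r}\t"
                 f"n_markers_used={grm.n_markers_used}\t"
                 f"excluded_markers={grm.excluded_markers}\n")
        fh.write("id\t" + "\t".join(grm.sample_ids) + "\n")
        for i, s in enumerate(grm.sample_ids):
            fh.write(s + "\t" + "\t".join(repr(float(v)) for v in grm.matrix[i]) + "\n")


def read_grm_tsv(path: str | Path) -> GRM:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(item.split("=") for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return GRM(sample_ids=[str(s) for s in df.index],
               matrix=df.to_numpy(dtype=float),
               scaling_constant=float(meta["scaling_constant"]),
               n_markers_used=int(meta["n_markers_used"]),
               excluded_markers=int(meta["excluded_markers"]))


def write_grm_binary(grm: GRM, stem: str | Path) -> None:
    """Compact pair: `<stem>.ids` (one id per line, first line is metadata)
    and `<stem>.bin` (float64 lower triangle incl. diagonal, row-major)."""
    stem = Path(stem)
    with open(stem.with_suffix(".ids"), "w") as fh:
        fh.write(f"#scaling_constant={grm.scaling_constant!r}\t"
                 f"n_markers_used={grm.n_markers_used}\t"
                 f"excluded_markers={grm.excluded_markers}\n")
        fh.write("\n".join(grm.sample_ids) + "\n")
    n = grm.n_individuals
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype(np.float64).tofile(stem.with_suffix(".bin"))


def read_grm_binary(stem: str | Path) -> GRM:
    stem = Path(stem)
    with open(stem.with_suffix(".ids")) as fh:
        meta = dict(item.split("=") for item in fh.readline().strip().lstrip("#").split("\t"))
        ids = [line.strip() for line in fh if line.strip()]
    n = len(ids)
    tri = np.fromfile(stem.with_suffix(".bin"), dtype=np.float64)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("GRM binary size inconsistent with the ids file")
    M = np.zeros((n, n))
    M[np.tril_indices(n)] = tri
    M = M + M.T - np.diag(np.diag(M))
    return GRM(sample_ids=ids, matrix=M,
               scaling_constant=float(meta["scaling_constant"]),
               n_markers_used=int(meta["n_markers_used"]),
               excluded_markers=int(meta["excluded_markers"]))


def read_grm(path: str | Path) -> GRM:
    name = str(path)
    if name.endswith((".bin", ".ids")):
        return read_grm_binary(Path(name).with_suffix(""))
    return read_grm_tsv(path)


# ---------------------------------------------------------------------------
# variance components and GEBVs
# ---------------------------------------------------------------------------

def varcomp_to_dict(vc: VarCompUV | VarCompMV) -> dict:
    if isinstance(vc, VarCompUV):
        return {
            "kind": "uv",
            "sigma2_a": vc.sigma2_a, "sigma2_e": vc.sigma2_e, "h2": vc.h2,
            "se_sigma2_a": vc.se_sigma2_a, "se_sigma2_e": vc.se_sigma2_e,
            "se_h2": vc.se_h2, "loglik": vc.loglik, "n_iter": vc.n_iter,
            "converged": vc.converged, "boundary": vc.boundary,
        }
    return {
        "kind": "mv",
        "trait_names": vc.trait_names,
        "M": vc.M.tolist(), "R": vc.R.tolist(),
        "genetic_corr": vc.genetic_corr.tolist(),
        "se_M": vc.se_M.tolist(), "se_R": vc.se_R.tolist(),
        "se_genetic_corr": vc.se_genetic_corr.tolist(),
        "loglik": vc.loglik, "n_iter": vc.n_iter, "converged": vc.converged,
    }


def write_varcomp(vc: VarCompUV | VarCompMV, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(varcomp_to_dict(vc), fh, indent=2, allow_nan=True)
        fh.write("\n")


def read_varcomp(path: str | Path) -> VarCompUV | VarCompMV:
    with open(path) as fh:
        d = json.load(fh)
    if d["kind"] == "uv":
        return VarCompUV(sigma2_a=d["sigma2_a"], sigma2_e=d["sigma2_e"], h2=d["h2"],
                         se_sigma2_a=d["se_sigma2_a"], se_sigma2_e=d["se_sigma2_e"],
                         se_h2=d["se_h2"], loglik=d["loglik"], n_iter=d["n_iter"],
                         converged=d["converged"], boundary=d["boundary"])
    return VarCompMV(trait_names=d["trait_names"],
                     M=np.array(d["M"]), R=np.array(d["R"]),
                     genetic_corr=np.array(d["genetic_corr"]),
                     se_M=np.array(d["se_M"]), se_R=np.array(d["se_R"]),
                     se_genetic_corr=np.array(d["se_genetic_corr"]),
                     loglik=d["loglik"], n_iter=d["n_iter"], converged=d["converged"])


def write_gebv(gebv: pd.DataFrame, path: str | Path) -> None:
    gebv.to_csv(path, sep="\t", index=False)


def read_gebv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["id"] = df["id"].astype(str)
    return df
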