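"""File I/O: VCF, sample/truth/depth TSVs and YAML simulation configs.

All coordinates are 1-based inclusive (VCF convention). Chromosome names are
free text; the Z chromosome is always identified by an explicit flag, never
guessed. Writers and readers round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, validate_sample_table
from .zwsim import ArtifactSpec, LocusTruth, SimConfig

logger = logging.getLogger(__name__)

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT -> dosage coding
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)
_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF (v4.x, GT field).

    Multi-allelic or non-SNP records are skipped and counted. Phased
    genotypes are read by zygosity (``0|1`` is heterozygous).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, cols = [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        rows.append(
            (variant.CHROM, variant.POS, variant.ID or f"{variant.CHROM}:{variant.POS}",
             variant.REF, variant.ALT[0])
        )
        cols.append(_GT_TYPE_TO_DOSAGE[variant.gt_types])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    calls = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(calls, loci, samples)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (unphased GT, './.' for missing)."""
    path = Path(path)
    contigs = list(dict.fromkeys(matrix.loci["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zwscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples) + "\n"
        )
        for j in range(matrix.n_loci):
            row = matrix.loci.iloc[j]
            gts = "\t".join(_DOSAGE_TO_GT[int(g)] for g in matrix.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_samples(path: str | Path, matrix: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Read a sample TSV (id, population, sex; '#' comments allowed).

    A missing sex column yields all-'U'. When a matrix is given, the table
    is aligned to its sample order; any mismatch between the two sample
    sets is an error listing the symmetric difference.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: sample table needs an 'id' column")
    if "population" not in df.columns:
        df["population"] = "pop"
    if "sex" not in df.columns:
        df["sex"] = "U"
    df["sex"] = df["sex"].fillna("U").replace("", "U")
    df = df[["id", "population", "sex"] + [c for c in df.columns if c not in ("id", "population", "sex")]]
    validate_sample_table(df)
    if matrix is not None:
        tsv_ids, vcf_ids = set(df["id"]), set(matrix.samples)
        if tsv_ids != vcf_ids:
            only_tsv = sorted(tsv_ids - vcf_ids)
            only_vcf = sorted(vcf_ids - tsv_ids)
            raise ValueError(
                f"sample sets differ — only in TSV: {only_tsv}; only in VCF: {only_vcf}"
            )
        df = df.set_index("id").loc[matrix.samples].reset_index()
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_truth(truth: list[LocusTruth], path: str | Path) -> None:
    rows = []
    for t in truth:
        freqs = (
            ";".join(f"{k}={v:.17g}" for k, v in t.p_pop.items()) if t.p_pop else ""
        )
        rows.append((t.locus_id, t.locus_class, freqs, t.coverage_multiplier))
    pd.DataFrame(
        rows, columns=["id", "class", "p_pop", "coverage_multiplier"]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[LocusTruth]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str, "class": str})
    out = []
    for _, row in df.iterrows():
        p_pop = None
        if isinstance(row["p_pop"], str) and row["p_pop"]:
            p_pop = dict(
                (k, float(v)) for k, v in (kv.split("=") for kv in row["p_pop"].split(";"))
            )
        out.append(LocusTruth(row["id"], row["class"], p_pop, float(row["coverage_multiplier"])))
    return out


def write_depth(depth: np.ndarray, matrix: GenotypeMatrix, path: str | Path) -> None:
    """Depth TSV: one row per individual, one column per locus id."""
    pd.DataFrame(depth, index=pd.Index(matrix.samples, name="id"),
                 columns=matrix.loci["id"]).to_csv(path, sep="\t")


def read_depth(path: str | Path, matrix: GenotypeMatrix | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="id")
    if matrix is not None:
        df = df.loc[matrix.samples, matrix.loci["id"]]
    return df.to_numpy()


def load_sim_config(path: str | Path, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file plus keyword overrides.

    Populations are listed as ``[{name, males, females}, ...]``; artifact
    loci as ``[{chrom, pos, regime, coverage_multiplier}, ...]``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    pops = [(p["name"], p["males"], p["females"]) for p in raw.pop("populations")]
    artifacts = [
        ArtifactSpec(
            a["chrom"], a["pos"], a["regime"], a.get("coverage_multiplier", 6.0)
        )
        for a in raw.pop("artifact_loci", [])
    ]
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimConfig(populations=pops, artifact_loci=artifacts, **raw)


def file_digest(path: str | Path) -> str:
    """Short sha256 digest of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]
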