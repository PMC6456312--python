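"""Readers and writers for the toolkit's tabular formats.

Phenotypes travel as CSV (replicate-level: ``strain, replicate, value``
plus optional ``sex`` and covariates; line-level: ``line, value``).
Genotypes are read from minimal VCF (homozygous diploid GTs ``0/0`` and
``1/1``, ``./.`` missing) or a line × SNP allele-count TSV.  Founder
haplotype probabilities round-trip through a long-format TSV
(``ril, chrom, position_cM, founder, probability``) or an NPZ array
container.  Ground-truth records serialize to JSON.

Coordinate conventions: genetic-map positions are centiMorgans and
chromosome-scoped; VCF positions are 1-based per the standard.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FounderHaplotypeMatrix, GenotypeMatrix, SimTruth

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "read_haplotypes_npz",
    "write_haplotypes_npz",
    "read_truth_json",
    "write_truth_json",
]

_SCHEMAS = {
    "replicate": ["strain", "replicate", "value"],
    "ril": ["strain", "value"],
    "line": ["line", "value"],
}


def read_phenotypes(
    path: str | Path, schema: str = "replicate", strain_means: bool = False
) -> pd.DataFrame | pd.Series:
    """Validated phenotype table from CSV.

    ``schema`` is one of ``replicate`` (strain, replicate, value plus
    optional columns), ``ril`` or ``line`` (id, value).  With
    ``strain_means=True`` replicate rows are averaged per strain and a
    Series indexed by strain is returned.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    required = _SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing required columns: {missing}")
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(f"non-numeric trait value at data row {row}")
    df["value"] = pd.to_numeric(df["value"])
    id_col = "line" if schema == "line" else "strain"
    if strain_means:
        return df.groupby(id_col)["value"].mean()
    if schema in ("ril", "line"):
        return pd.Series(
            df["value"].to_numpy(), index=df[id_col], name="value"
        )
    return df


def write_phenotypes(df: pd.DataFrame | pd.Series, path: str | Path) -> None:
    if isinstance(df, pd.Series):
        df = df.rename("value").rename_axis("strain").reset_index()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(
    path: str | Path, format: str | None = None, maf_min: float = 0.05
) -> GenotypeMatrix:
    """Genotype matrix from VCF or TSV, MAF-filtered.

    Heterozygous or multiallelic VCF records are skipped (the panels are
    inbred); sites with MAF below ``maf_min`` are removed.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        geno = _read_vcf(path)
    elif format == "tsv":
        geno = _read_geno_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return geno.filter_maf(maf_min)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = np.array(vcf.samples)
    snp_ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.genotype.array()[:, :2]
        col = np.full(len(lines), np.nan)
        hom_ref = (gts == 0).all(axis=1)
        hom_alt = (gts == 1).all(axis=1)
        het = (gts >= 0).all(axis=1) & ~hom_ref & ~hom_alt
        if het.any():
            n_skipped += 1
            continue
        col[hom_ref] = 0.0
        col[hom_alt] = 2.0
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(col)
    vcf.close()
    if not cols:
        raise ValueError(f"no usable biallelic homozygous sites in {path}")
    return GenotypeMatrix(
        line_ids=lines,
        snp_ids=np.array(snp_ids),
        chrom=np.array(chroms),
        pos=np.array(poss),
        counts=np.column_stack(cols),
        ref=np.array(refs),
        alt=np.array(alts),
    )


def _read_geno_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_rows = {"chrom", "pos", "ref", "alt"}
    meta = df.loc[[r for r in df.index if r in meta_rows]]
    body = df.loc[[r for r in df.index if r not in meta_rows]]
    counts = body.to_numpy(dtype=float)
    return GenotypeMatrix(
        line_ids=body.index.to_numpy(),
        snp_ids=df.columns.to_numpy(),
        chrom=meta.loc["chrom"].to_numpy() if "chrom" in meta.index else np.full(df.shape[1], "."),
        pos=(
            meta.loc["pos"].to_numpy(dtype=int)
            if "pos" in meta.index
            else np.arange(1, df.shape[1] + 1)
        ),
        counts=counts,
        ref=meta.loc["ref"].to_numpy() if "ref" in meta.index else None,
        alt=meta.loc["alt"].to_numpy() if "alt" in meta.index else None,
    )


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Line × SNP allele-count TSV with chrom/pos/ref/alt header rows."""
    frame = geno.to_frame()
    meta = pd.DataFrame(
        [geno.chrom, geno.pos, geno.ref, geno.alt],
        index=["chrom", "pos", "ref", "alt"],
        columns=frame.columns,
    )
    pd.concat([meta, frame]).to_csv(path, sep="\t")


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF with homozygous diploid genotypes (0/0, 1/1, ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [str(s) for s in geno.line_ids]
        fh.write("\t".join(header) + "\n")
        order = np.lexsort((geno.pos, geno.chrom))
        for j in order:
            gts = []
            for c in geno.counts[:, j]:
                if np.isnan(c):
                    gts.append("./.")
                elif c == 0:
                    gts.append("0/0")
                else:
                    gts.append("1/1")
            row = [
                str(geno.chrom[j]),
                str(int(geno.pos[j])),
                str(geno.snp_ids[j]),
                str(geno.ref[j]),
                str(geno.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ] + gts
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# haplotype probabilities

def write_haplotypes_tsv(haps: FounderHaplotypeMatrix, path: str | Path) -> None:
    """Long-format TSV: ril, chrom, position_cM, founder, probability."""
    n, p, k = haps.probs.shape
    df = pd.DataFrame(
        {
            "ril": np.repeat(haps.rils, p * k),
            "chrom": np.tile(np.repeat(haps.chrom, k), n),
            "position_cM": np.tile(np.repeat(haps.positions, k), n),
            "founder": np.tile(haps.founders, n * p),
            "probability": haps.probs.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path: str | Path) -> FounderHaplotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"ril", "chrom", "position_cM", "founder", "probability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"haplotype file missing columns: {sorted(missing)}")
    rils = pd.unique(df["ril"])
    founders = list(pd.unique(df["founder"]))
    pos_tbl = df.drop_duplicates(["chrom", "position_cM"])[["chrom", "position_cM"]]
    positions = pos_tbl["position_cM"].to_numpy(dtype=float)
    chrom = pos_tbl["chrom"].to_numpy()
    n, p, k = len(rils), len(positions), len(founders)
    probs = df["probability"].to_numpy(dtype=float).reshape(n, p, k)
    return FounderHaplotypeMatrix(
        rils=np.asarray(rils), chrom=chrom, positions=positions, probs=probs,
        founders=founders,
    )


def write_haplotypes_npz(haps: FounderHaplotypeMatrix, path: str | Path) -> None:
    np.savez_compressed(
        path,
        rils=haps.rils.astype(str),
        chrom=haps.chrom.astype(str),
        positions=haps.positions,
        probs=haps.probs,
        founders=np.array(haps.founders, dtype=str),
    )


def read_haplotypes_npz(path: str | Path) -> FounderHaplotypeMatrix:
    with np.load(path, allow_pickle=False) as z:
        return FounderHaplotypeMatrix(
            rils=z["rils"],
            chrom=z["chrom"],
            positions=z["positions"],
            probs=z["probs"],
            founders=list(z["founders"]),
        )


# ---------------------------------------------------------------------------
# ground truth

def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "qtl_positions": list(truth.qtl_positions),
        "founder_effects": [list(map(float, e)) for e in truth.founder_effects],
        "target_h2": truth.target_h2,
        "causal_snps": truth.causal_snps,
        "study_params": truth.study_params,
        "seed": truth.seed,
        "env_sd": truth.env_sd,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth_json(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    env_sd = payload.pop("env_sd", None)
    truth = SimTruth(**payload)
    truth.env_sd = env_sd
    return truth
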