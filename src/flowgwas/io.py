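"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCFv4.2 (read with cyvcf2; DS dosage field
preferred, GT summed otherwise), phenotype/covariate tables and summary
statistics as tab-separated text.  Coordinates follow the usual
conventions: VCF and TSV positions are 1-based inclusive, BED intervals
0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import GenotypeMatrix

SUMSTAT_COLUMNS = ["chrom", "pos", "ref", "alt", "beta", "se", "p", "n", "maf", "info"]


def write_vcf(g: GenotypeMatrix, path: str | Path, field: str = "DS") -> Path:
    """Write a dosage matrix as minimal VCFv4.2 (DS or GT records)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if field == "DS":
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        else:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO score">\n')
        for chrom in pd.unique(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
        for j in order:
            v = g.variants.iloc[j]
            dos = g.dosages[:, j]
            if field == "DS":
                cells = ["." if np.isnan(d) else f"{d:g}" for d in dos]
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}
                cells = ["./." if np.isnan(d) else gt[int(round(d))] for d in dos]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\t.\t"
                f"INFO={v['info']:g}\t{field}\t" + "\t".join(cells) + "\n"
            )
    return path


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (DS preferred, GT summed).

    Missing entries become NaN with the variant retained; a malformed
    file raises with as much location information as the parser gives.
    """
    from cyvcf2 import VCF

    path = str(path)
    _check_vcf_header(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    meta = []
    for rec in vcf:
        fmts = rec.FORMAT
        if "DS" in fmts:
            ds = np.array(rec.format("DS"), dtype=float).reshape(-1)
        else:
            gts = np.array(rec.genotype.array())[:, :2].astype(float)
            gts[gts < 0] = np.nan
            ds = gts.sum(axis=1)
        info = dict(rec.INFO).get("INFO", 1.0)
        freq = np.nanmean(ds) / 2.0
        meta.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "maf": float(min(freq, 1 - freq)),
                "info": float(info),
            }
        )
        rows.append(ds)
    dosages = np.array(rows).T if rows else np.zeros((len(samples), 0))
    return GenotypeMatrix(dosages=dosages, variants=pd.DataFrame(meta), samples=samples)


def _check_vcf_header(path: str) -> None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                return
            if not line.startswith("##"):
                break
    raise ValueError(f"{path}: malformed VCF, no #CHROM header line")


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["id"] + [c for c in SUMSTAT_COLUMNS if c in stats.columns]
    stats[cols].to_csv(path, sep="\t", index=False)
    return path


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(windows: list[tuple[str, int, int]], path: str | Path) -> Path:
    """Write windows as BED (0-based, half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end in windows:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path


def write_trait_registry(specs: list, path: str | Path) -> Path:
    """Persist trait specifications (name, support, kind, derivation,
    cell type) as a TSV registry."""
    rows = [
        {
            "name": s.name,
            "support": s.support,
            "kind": s.kind,
            "derivation": s.derivation,
            "cell_type": s.cell_type,
        }
        for s in specs
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_trait_registry(path: str | Path) -> list:
    from .phenoadjust import TraitSpec

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        TraitSpec(
            name=r["name"],
            support=r["support"],
            kind=r["kind"],
            derivation=r["derivation"],
            cell_type=r["cell_type"],
        )
        for _, r in df.iterrows()
    ]


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
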