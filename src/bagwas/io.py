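"""Readers and writers for the toolkit's on-disk formats.

Dosage genotypes travel as VCF with a FORMAT/DS field; summary statistics
as COJO ``.ma`` tables (SNP A1 A2 freq b se p N); gene models as GFF3
(1-based inclusive) or BED (0-based half-open); QTL/score/GO fixtures and
cohort tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .syndata import GenotypePanel

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def write_ma(df: pd.DataFrame, path) -> None:
    df[MA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ma(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    missing = set(MA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing .ma columns {sorted(missing)}")
    return df


def sumstats_to_ma(sumstats: pd.DataFrame) -> pd.DataFrame:
    """Convert an internal summary-statistics table to .ma layout."""
    return pd.DataFrame({
        "SNP": sumstats["id"],
        "A1": sumstats["a1"],
        "A2": sumstats["a2"],
        "freq": sumstats["freq_a1"],
        "b": sumstats["beta"],
        "se": sumstats["se"],
        "p": sumstats["p"],
        "N": sumstats["n"],
    })


def ma_to_sumstats(ma: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Attach panel coordinates to a .ma table."""
    pv = panel.variants.set_index("id")
    out = ma.copy()
    out["chrom"] = pv.loc[out["SNP"], "chrom"].to_numpy()
    out["pos"] = pv.loc[out["SNP"], "pos"].to_numpy()
    return out.rename(columns={"SNP": "id", "A1": "a1", "A2": "a2", "freq": "freq_a1",
                               "b": "beta", "se": "se", "p": "p", "N": "n"})


def write_vcf_ds(panel: GenotypePanel, path) -> None:
    """VCF 4.2 with per-sample FORMAT/DS dosages (REF = a2, ALT = a1)."""
    n = panel.n_individuals
    samples = [f"I{i:05d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        for chrom in panel.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, (_, v) in enumerate(panel.variants.iterrows()):
            ds = "\t".join(f"{d:.3f}" for d in panel.dosages[:, j])
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['a2']}\t{v['a1']}\t.\tPASS\t"
                     f"INFO={v['info']:.2f}\tDS\t{ds}\n")


def read_vcf_ds(path) -> GenotypePanel:
    """Read a DS-format VCF back into a panel (ALT is the effect allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, cols = [], []
    for rec in vcf:
        ds = np.asarray(rec.format("DS"), dtype=float).ravel()
        cols.append(ds)
        rows.append({
            "chrom": rec.CHROM, "pos": rec.POS, "id": rec.ID,
            "a1": rec.ALT[0], "a2": rec.REF,
            "ploidy_class": {"1": "diploid", "X": "chrX", "Y": "chrY", "XY": "chrXY"}.get(rec.CHROM, "diploid"),
            "info": float(rec.INFO.get("INFO", 1.0)),
        })
    dos = np.column_stack(cols)
    variants = pd.DataFrame(rows)
    scale = 1 if (variants["ploidy_class"] == "chrY").all() else 2
    freq = dos.mean(axis=0) / scale
    variants["maf"] = np.minimum(freq, 1 - freq)
    # between-block gaps are generator metadata; infer blocks from position jumps
    pos = variants["pos"].to_numpy()
    block = np.zeros(len(variants), dtype=int)
    for j in range(1, len(variants)):
        jump = (variants["chrom"].iloc[j] != variants["chrom"].iloc[j - 1]) or (pos[j] - pos[j - 1] > 1_000_000)
        block[j] = block[j - 1] + (1 if jump else 0)
    return GenotypePanel(variants=variants, dosages=dos, block_index=block)


def write_bed(genes: pd.DataFrame, path) -> None:
    """BED6: 0-based half-open intervals."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            fh.write(f"{g['chrom']}\t{g['start'] - 1}\t{g['end']}\t{g['symbol']}\t0\t{g['strand']}\n")


def write_gff3(genes: pd.DataFrame, path) -> None:
    """GFF3 gene + exon records, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID=gene:{g['symbol']};Name={g['symbol']}"
            fh.write(f"{g['chrom']}\tbagwas\tgene\t{g['start']}\t{g['end']}\t.\t{g['strand']}\t.\t{attrs}\n")
            starts = str(g.get("exon_starts", "")).split(";")
            ends = str(g.get("exon_ends", "")).split(";")
            for k, (s, e) in enumerate(zip(starts, ends)):
                if s and e:
                    fh.write(f"{g['chrom']}\tbagwas\texon\t{s}\t{e}\t.\t{g['strand']}\t.\t"
                             f"ID=exon:{g['symbol']}.{k};Parent=gene:{g['symbol']}\n")


def read_gff3_genes(path) -> pd.DataFrame:
    """Collect gene + exon records from a GFF3 written by this package."""
    genes, exons = {}, {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if f[2] == "gene":
                sym = attrs["Name"]
                genes[sym] = {"chrom": f[0], "start": int(f[3]), "end": int(f[4]),
                              "strand": f[6], "symbol": sym}
            elif f[2] == "exon":
                sym = attrs["Parent"].split(":", 1)[1]
                exons.setdefault(sym, []).append((int(f[3]), int(f[4])))
    rows = []
    for sym, g in genes.items():
        ex = sorted(exons.get(sym, []))
        g["exon_starts"] = ";".join(str(s) for s, _ in ex)
        g["exon_ends"] = ";".join(str(e) for _, e in ex)
        g["cds_start"], g["cds_end"] = g["start"], g["end"]
        rows.append(g)
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def write_cohort(cohort, out_dir) -> None:
    """Cohort covariate table plus feature matrices as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.table.assign(bag_true=cohort.bag_true).to_csv(out / "cohort.tsv", sep="\t", index=False)
    for name, mat in (("features_gm", cohort.features_gm), ("features_wm", cohort.features_wm)):
        pd.DataFrame(mat, columns=[f"f{j}" for j in range(mat.shape[1])]).to_csv(
            out / f"{name}.tsv", sep="\t", index=False)
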