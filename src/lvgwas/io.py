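"""Readers and writers for the pipeline's on-disk formats.

Formats are plain text throughout: a two-file TSV "matrix" format for
genotype panels, minimal VCF 4.2 with a DS (dosage) FORMAT field, TSV
summary statistics, and BED-like gene maps (0-based half-open on disk,
converted to the package's internal 1-based inclusive convention on read).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import SUMSTATS_COLUMNS
from .panel import GenotypePanel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- matrix format

def write_genotypes_matrix(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel as ``<prefix>.variants.tsv`` + ``<prefix>.dosages.tsv``."""
    prefix = Path(prefix)
    vpath = Path(str(prefix) + ".variants.tsv")
    dpath = Path(str(prefix) + ".dosages.tsv")
    panel.variants.to_csv(vpath, sep="\t", index=False)
    dos = pd.DataFrame(panel.dosages, columns=panel.variants["id"])
    dos.insert(0, "sample_id", panel.samples)
    dos.to_csv(dpath, sep="\t", index=False, float_format="%.6g")
    return vpath, dpath


def read_genotypes_matrix(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    variants = pd.read_csv(Path(str(prefix) + ".variants.tsv"), sep="\t")
    dos = pd.read_csv(Path(str(prefix) + ".dosages.tsv"), sep="\t")
    samples = dos["sample_id"].astype(str).tolist()
    dosages = dos.drop(columns="sample_id").to_numpy(dtype=float)
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


# ------------------------------------------------------------------------- VCF

def write_vcf(panel: GenotypePanel, path: str | Path) -> Path:
    """Write a minimal uncompressed VCF 4.2 with GT (hard call) and DS."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j in range(panel.n_variants):
            v = panel.variants.iloc[j]
            info = f"INFO={v['info']:.4f}"
            cells = []
            for d in panel.dosages[:, j]:
                hard = int(np.clip(np.rint(d), 0, 2))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[hard]
                cells.append(f"{gt}:{d:.3f}")
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\tPASS\t"
                f"{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )
    return path


def read_vcf(path: str | Path, skip_multiallelic: bool = True) -> GenotypePanel:
    """Read a plain-text VCF into a panel.

    Dosages come from the DS FORMAT field when present, otherwise from the
    GT allele sum.  Multi-allelic records are skipped (logged) or rejected
    per ``skip_multiallelic``.  Malformed records raise with the line number.
    """
    path = Path(path)
    samples: list[str] = []
    var_rows = []
    dosage_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: malformed VCF record (<10 fields)")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                if skip_multiallelic:
                    log.warning("%s:%d: skipping multi-allelic site %s", path, lineno, vid)
                    continue
                raise ValueError(f"{path}:{lineno}: multi-allelic site {vid}")
            fmt = fields[8].split(":")
            try:
                ds_i = fmt.index("DS")
            except ValueError:
                ds_i = None
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                gt_i = None
            if ds_i is None and gt_i is None:
                raise ValueError(f"{path}:{lineno}: record has neither DS nor GT")
            row = []
            for cell in fields[9:]:
                parts = cell.split(":")
                try:
                    if ds_i is not None:
                        row.append(float(parts[ds_i]))
                    else:
                        gt = parts[gt_i].replace("|", "/")
                        row.append(float(sum(int(a) for a in gt.split("/") if a != ".")))
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: bad genotype cell {cell!r}") from exc
            info_val = np.nan
            for kv in fields[7].split(";"):
                if kv.startswith("INFO="):
                    info_val = float(kv.split("=", 1)[1])
            dosage_rows.append(row)
            var_rows.append((vid, int(chrom), int(pos), ref, alt, np.nan, info_val, 1.0))
    dosages = np.array(dosage_rows, dtype=float).T
    variants = pd.DataFrame(
        var_rows,
        columns=["id", "chrom", "pos", "ref", "alt", "maf", "info", "call_rate"],
    )
    af = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(af, 1 - af)
    variants["info"] = variants["info"].fillna(1.0)
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def read_genotypes(path: str | Path, fmt: str = "matrix") -> GenotypePanel:
    """Dispatching genotype reader: ``fmt`` is ``"matrix"`` or ``"vcf"``."""
    if fmt == "matrix":
        return read_genotypes_matrix(path)
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# --------------------------------------------------------------- summary stats

def write_sumstats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in SUMSTATS_COLUMNS if c in stats.columns]
    stats[cols].to_csv(path, sep="\t", index=False)
    return path


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("ID", "EA", "NEA", "BETA", "P") if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics file missing columns: {missing}")
    return df


# -------------------------------------------------------------------- gene map

def write_gene_map(gene_map: pd.DataFrame, path: str | Path) -> Path:
    """Write the internal (1-based inclusive) gene map as BED-like TSV
    (0-based half-open): start - 1, end unchanged."""
    out = gene_map.copy()
    out["start"] = out["start"].astype(int) - 1
    out[["chrom", "start", "end", "gene", "panel_flag"]].to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene map and convert to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    req = ["chrom", "start", "end", "gene"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"gene map missing columns: {missing}")
    df = df.copy()
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    if "panel_flag" not in df.columns:
        df["panel_flag"] = 0
    return df


def read_gene_panel(path: str | Path) -> list[str]:
    """One-gene-per-line Mendelian panel list."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_panel(genes: list[str], path: str | Path) -> Path:
    Path(path).write_text("\n".join(genes) + "\n")
    return Path(path)
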