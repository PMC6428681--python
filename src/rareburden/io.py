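"""Readers and writers for the pipeline's tabular formats.

Tab-separated tables (UTF-8, header row) are the canonical interchange:
variant sites (carrier lists comma-joined), individuals, per-gene mutation
rates, de novo counts, and association results. Gene sets use the GMT
convention (set name, description, then gene symbols, tab-separated, one
set per line). A minimal sites-only VCF (one ALT per record; INFO keys
GENE, CLASS, PCONS, AC; 1-based coordinates) is supported as a convenience:
written as plain text, read through cyvcf2 when available.

Writers prepend ``#`` comment lines recording provenance (seed, package
version); ``read_tsv`` skips them.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

_LIST_SEP = ","


def _comment_header(seed=None) -> str:
    lines = [f"# rareburden {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, seed=None) -> None:
    df = df.copy()
    if "carriers" in df.columns:
        df["carriers"] = df["carriers"].map(
            lambda xs: _LIST_SEP.join(map(str, xs)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    if "carriers" in df.columns:
        df["carriers"] = df["carriers"].map(
            lambda s: [] if pd.isna(s) else str(s).split(_LIST_SEP))
    if "paralog_conserved" in df.columns:
        df["paralog_conserved"] = df["paralog_conserved"].map(
            lambda v: pd.NA if pd.isna(v) else bool(v))
    return df


def write_gmt(sets: dict, path) -> None:
    """Write {name: iterable of genes} in GMT format."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, f"{name} gene set", *map(str, genes)]))
            fh.write("\n")


def read_gmt(path) -> dict:
    """Read a GMT file into {set name: list of genes}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene-set file not found: {path}")
    out = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT lines need name, description and at "
                f"least one gene")
        out[fields[0]] = fields[2:]
    return out


def write_rate_table(rate_table: pd.DataFrame, path, seed=None) -> None:
    write_tsv(rate_table[["gene", "class", "mu"]], path, seed=seed)


def read_rate_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"gene", "class", "mu"} - set(df.columns)
    if missing:
        raise ValueError(f"rate table {path} lacks columns: {sorted(missing)}")
    return df


def write_vcf(variants: pd.DataFrame, path, contig: str = "1") -> None:
    """Write a minimal sites-only VCF (synthetic positions, one ALT/record)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=rareburden {__version__}\n")
        fh.write(f"##contig=<ID={contig}>\n")
        for key, desc in (("GENE", "Gene symbol"),
                          ("CLASS", "Mutation class"),
                          ("PCONS", "Paralog-conserved missense flag"),
                          ("AC", "Alternate allele count")):
            typ = "Integer" if key == "AC" else "String"
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},'
                     f'Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, row in enumerate(variants.itertuples(), start=1):
            pcons = ("." if pd.isna(row.paralog_conserved)
                     else str(int(bool(row.paralog_conserved))))
            info = (f"GENE={row.gene};CLASS={row.mclass};PCONS={pcons};"
                    f"AC={row.allele_count}")
            fh.write(f"{contig}\t{pos}\t{row.variant_id}\tA\tG\t.\tPASS\t"
                     f"{info}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a sites-only VCF into a variant table (no carrier lists)."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rows = []
    for rec in VCF(str(path)):
        pcons = rec.INFO.get("PCONS")
        rows.append({
            "variant_id": rec.ID,
            "gene": rec.INFO.get("GENE"),
            "mclass": rec.INFO.get("CLASS"),
            "paralog_conserved": (pd.NA if pcons in (None, ".")
                                  else bool(int(pcons))),
            "allele_count": int(rec.INFO.get("AC", 0)),
            "carriers": [],
        })
    return pd.DataFrame(rows)


def read_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
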