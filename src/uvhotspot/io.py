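"""Tabular file formats: BED6 reads, capture regions, mutation catalogs,
motif-site tables and TSS tables.

Internally everything is 0-based half-open; TSV reports use 1-based
positions (`pos` columns), converted on read/write.
"""

from __future__ import annotations

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

CATALOG_COLUMNS = [
    "contig", "position", "ref", "alt", "tumor_count", "class", "gene",
    "cancer_gene",
]


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=BED6_COLUMNS, dtype={"chrom": "category", "strand": "category"},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"malformed strand value {df['strand'][bad].iloc[0]!r} in {path}"
        )
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_regions(path) -> pd.DataFrame:
    """Capture regions: BED6 with the region class carried in a 7th column
    (falling back to the name field when absent)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: expected >=6 BED columns")
    df = df.iloc[:, :7]
    df.columns = BED6_COLUMNS + (["class"] if df.shape[1] == 7 else [])
    if "class" not in df:
        df["class"] = df["name"]
    return df


def write_regions(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS + ["class"]].to_csv(path, sep="\t", header=False,
                                        index=False)


def read_catalog(path) -> pd.DataFrame:
    """Recurrent-mutation catalog TSV (1-based `pos` -> 0-based `position`)."""
    df = pd.read_csv(path, sep="\t")
    if "pos" in df.columns:
        df = df.rename(columns={"pos": "position"})
        df["position"] = df["position"].astype(int) - 1
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing catalog columns {sorted(missing)}")
    return df


def write_catalog(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(1, "pos", out.pop("position").astype(int) + 1)
    out.to_csv(path, sep="\t", index=False)


def read_vcf_catalog(path, default_class: str = "promoter") -> pd.DataFrame:
    """Map a (single-sample, SNV) VCF onto the mutation-catalog schema.

    ``tumor_count`` is taken from the INFO field ``TC`` when present,
    else from ``AC``, else 1; ``gene`` from INFO ``GENE`` (empty string
    otherwise).  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if v.ALT is None or len(v.REF) != 1:
            continue
        for alt in v.ALT:
            if len(alt) != 1:
                continue
            tc = v.INFO.get("TC") or v.INFO.get("AC") or 1
            if isinstance(tc, tuple):
                tc = tc[0]
            rows.append({
                "contig": v.CHROM, "position": v.POS - 1, "ref": v.REF,
                "alt": alt, "tumor_count": int(tc),
                "class": v.INFO.get("CLASS") or default_class,
                "gene": v.INFO.get("GENE") or "",
                "cancer_gene": bool(v.INFO.get("CANCER_GENE", False)),
            })
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def read_tss(path) -> pd.DataFrame:
    """TSS table: gene, contig, pos (1-based) -> 0-based `position`."""
    df = pd.read_csv(path, sep="\t")
    if "pos" in df.columns:
        df = df.rename(columns={"pos": "position"})
        df["position"] = df["position"].astype(int) - 1
    for col in ("gene", "contig", "position"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing TSS column {col!r}")
    return df


def write_tss(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos"] = out.pop("position").astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_sites(path) -> pd.DataFrame:
    """Motif-site table TSV (1-based `midpoint_pos` -> 0-based `midpoint`)."""
    df = pd.read_csv(path, sep="\t")
    if "midpoint_pos" in df.columns:
        df = df.rename(columns={"midpoint_pos": "midpoint"})
        df["midpoint"] = df["midpoint"].astype(int) - 1
    return df


def write_sites(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["midpoint_pos"] = out.pop("midpoint").astype(int) + 1
    out.to_csv(path, sep="\t", index=False)
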