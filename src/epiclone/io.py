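"""Delimited-text I/O for clone tables, intensity tables and variant tables.

All tables are tab-separated UTF-8 with a header row.  Column contracts:

clone table
    animal_id, genotype, time_weeks, n_basal, n_suprabasal
intensity table
    animal_id, time_weeks, log2_intensity
variant table
    chrom, pos, ref, alt, biopsy_id, mouse_id, exposure, p_value,
    fwd_reads, rev_reads  (optional: alt_count, depth)

Variant records may alternatively arrive as a minimal VCF v4.x with INFO
fields ``PV`` (raw p-value), ``FWD`` and ``REV`` (per-strand supporting
reads) and per-record ``MOUSE``/``EXPOSURE`` labels; see
:func:`read_variant_vcf`.
"""

from __future__ import annotations

import io as _io

import pandas as pd

CLONE_COLUMNS = ["animal_id", "genotype", "time_weeks", "n_basal", "n_suprabasal"]
INTENSITY_COLUMNS = ["animal_id", "time_weeks", "log2_intensity"]
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "biopsy_id",
    "mouse_id",
    "exposure",
    "p_value",
    "fwd_reads",
    "rev_reads",
]

EXPOSURE_LABELS = ("irradiated", "unexposed")


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_clone_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CLONE_COLUMNS, "clone table")
    return df


def write_clone_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, CLONE_COLUMNS, "clone table")
    df.to_csv(path, sep="\t", index=False)


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, INTENSITY_COLUMNS, "intensity table")
    return df


def write_intensity_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, INTENSITY_COLUMNS, "intensity table")
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, VARIANT_COLUMNS, "variant table")
    return df


def write_variant_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, VARIANT_COLUMNS, "variant table")
    df.to_csv(path, sep="\t", index=False)


def read_variant_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF v4.x into the variant-table column contract.

    Expected INFO keys per record: PV (float p-value), FWD, REV (int strand
    read counts), MOUSE (mouse id), EXPOSURE (irradiated|unexposed),
    BIOPSY (biopsy id).  Requires pysam.
    """
    import pysam  # optional dependency, VCF dialect only

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "biopsy_id": str(info["BIOPSY"]),
                    "mouse_id": str(info["MOUSE"]),
                    "exposure": str(info["EXPOSURE"]),
                    "p_value": float(info["PV"]),
                    "fwd_reads": int(info["FWD"]),
                    "rev_reads": int(info["REV"]),
                }
            )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def read_kv(path) -> dict:
    """Read a flat, comment-tolerant key=value file into a dict of strings."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            out[key.strip()] = raw.strip()
    return out


def write_kv(mapping: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in mapping.items():
            fh.write(f"{key} = {value}\n")


def table_to_string(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
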