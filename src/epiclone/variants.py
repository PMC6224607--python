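"""Somatic variant filtering for paired deep-sequenced biopsies.

Candidate variant calls from ultra-deep targeted sequencing are dominated by
artifacts.  The pipeline applies, in order:

1. **paired-sharing removal** — a variant observed at the same site
   (chrom, pos, ref, alt) in biopsies from *both* exposure arms of the same
   mouse is germline or a systematic artifact, not an independent somatic
   event, and is dropped everywhere it occurs;
2. **Benjamini–Hochberg step-up FDR control** on the caller's per-variant
   p-values, applied within each mouse as its own family (optionally within
   each biopsy), keeping calls with q < ``q_max``;
3. **strand filter** — at least ``min_forward`` forward and ``min_reverse``
   reverse supporting reads, removing strand-specific artifacts.

The BH step-up is hand-rolled here because the grouped, ordered q-value is
the quantity under test; the test suite cross-checks it against
statsmodels' implementation to 1e-12.

Burden and spectrum summaries follow deep-sequencing conventions: burden is
mutations per mm^2 of biopsy area, and single-nucleotide spectra are
collapsed onto the pyrimidine strand (six substitution classes) so that a
UV signature appears as a C>T excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "bh_qvalues",
    "drop_paired_shared",
    "bh_filter",
    "strand_filter",
    "run_filter_pipeline",
    "mutation_burden",
    "mutation_spectrum",
]

_SITE_KEYS = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering pipeline.

    ``group_by`` sets the BH family: "mouse_id" (default; one family per
    mouse) or "biopsy_id".
    """

    q_max: float = 0.1
    min_forward: int = 1
    min_reverse: int = 1
    group_by: str = "mouse_id"
    biopsy_area_mm2: float = 16.0

    def __post_init__(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValueError("q_max must be in (0, 1]")
        if self.min_forward < 0 or self.min_reverse < 0:
            raise ValueError("strand read minima must be >= 0")
        if self.group_by not in ("mouse_id", "biopsy_id"):
            raise ValueError("group_by must be 'mouse_id' or 'biopsy_id'")
        if self.biopsy_area_mm2 <= 0:
            raise ValueError("biopsy_area_mm2 must be positive")


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _check_columns(records: pd.DataFrame, needed: list[str]) -> None:
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"variant table is missing columns {missing}")


def drop_paired_shared(records: pd.DataFrame) -> pd.DataFrame:
    """Remove variants shared across exposure arms within a mouse.

    A site (chrom, pos, ref, alt) seen in >= 2 biopsies of one mouse that
    together span both exposure labels is treated as non-somatic and every
    record of it in that mouse is dropped.  Mice whose biopsies carry
    missing/ambiguous exposure labels raise rather than silently passing.
    """
    _check_columns(records, _SITE_KEYS + ["mouse_id", "exposure", "biopsy_id"])
    if len(records) == 0:
        return records.copy()
    exp = records["exposure"]
    bad = records.loc[exp.isna() | (exp == ""), "mouse_id"].unique()
    if len(bad):
        raise ValueError(f"missing exposure labels for mice {sorted(bad)}")
    n_exposures = records.groupby(["mouse_id"] + _SITE_KEYS)["exposure"].transform(
        "nunique"
    )
    return records.loc[n_exposures < 2].copy()


def bh_filter(records: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Grouped BH step-up; keep records with q < ``q_max``.

    Each group (mouse by default) is its own multiple-testing family; a
    ``q_value`` column is added.
    """
    config = config or FilterConfig()
    _check_columns(records, ["p_value", config.group_by])
    out = records.copy()
    if len(out) == 0:
        out["q_value"] = pd.Series(dtype=float)
        return out
    out["q_value"] = (
        out.groupby(config.group_by, group_keys=False)["p_value"]
        .transform(lambda p: bh_qvalues(p.to_numpy()))
    )
    return out.loc[out["q_value"] < config.q_max].copy()


def strand_filter(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Require support on both strands (>= min_forward and >= min_reverse)."""
    config = config or FilterConfig()
    _check_columns(records, ["fwd_reads", "rev_reads"])
    keep = (records["fwd_reads"] >= config.min_forward) & (
        records["rev_reads"] >= config.min_reverse
    )
    return records.loc[keep].copy()


def run_filter_pipeline(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: paired-sharing -> BH -> strand.

    Returns (survivors, attrition) where ``attrition`` lists the record
    count entering and leaving each stage.  Note the BH family is formed
    *after* shared-variant removal, so shared artifacts do not consume FDR
    budget.
    """
    config = config or FilterConfig()
    stages = [
        ("paired_shared", drop_paired_shared),
        ("bh_fdr", lambda df: bh_filter(df, config)),
        ("strand", lambda df: strand_filter(df, config)),
    ]
    rows = []
    current = records
    for name, fn in stages:
        n_in = len(current)
        current = fn(current)
        rows.append({"stage": name, "n_in": n_in, "n_out": len(current)})
    attrition = pd.DataFrame(rows, columns=["stage", "n_in", "n_out"])
    return current.reset_index(drop=True), attrition


def mutation_burden(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Mutations per biopsy and per mm^2, by biopsy with exposure carried.

    Biopsies absent from ``records`` (zero surviving mutations) are not
    listed; join against a biopsy manifest for explicit zeros.
    """
    config = config or FilterConfig()
    _check_columns(records, ["biopsy_id", "mouse_id", "exposure"])
    grouped = (
        records.groupby(["biopsy_id", "mouse_id", "exposure"], as_index=False)
        .size()
        .rename(columns={"size": "n_mutations"})
    )
    grouped["burden_per_mm2"] = grouped["n_mutations"] / config.biopsy_area_mm2
    return grouped


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def mutation_spectrum(records: pd.DataFrame) -> pd.Series:
    """Six-class SNV spectrum with pyrimidine-strand collapse.

    Substitutions whose reference base is a purine are complemented onto
    the pyrimidine strand (e.g. G>A counts as C>T).  Non-SNV records
    (indels, multi-base) are reported under ``non_snv`` and excluded from
    the class fractions; ``ct_fraction`` is the C>T share of SNVs.  Raises
    on an empty table rather than reporting a burden of zero.
    """
    _check_columns(records, ["ref", "alt"])
    if len(records) == 0:
        raise ValueError("mutation spectrum of an empty variant set is undefined")
    ref = records["ref"].astype(str).str.upper()
    alt = records["alt"].astype(str).str.upper()
    is_snv = (
        ref.isin(list("ACGT")) & alt.isin(list("ACGT")) & (ref != alt)
    )
    counts = dict.fromkeys(_CLASSES, 0)
    for r, a in zip(ref[is_snv], alt[is_snv]):
        if r in ("G", "A"):
            r, a = _COMPLEMENT[r], _COMPLEMENT[a]
        counts[f"{r}>{a}"] += 1
    n_snv = int(is_snv.sum())
    out = pd.Series(counts, dtype=float)
    if n_snv > 0:
        out = out / n_snv
    out["n_snv"] = float(n_snv)
    out["non_snv"] = float(len(records) - n_snv)
    out["ct_fraction"] = counts["C>T"] / n_snv if n_snv else np.nan
    out.name = "fraction"
    return out
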