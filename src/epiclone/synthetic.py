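"""Synthetic study-bundle generators with known ground truth.

Generates every input the analysis consumes — clone-count tables from the
single-progenitor process at the study's sampling times, H2BGFP intensity
chases, and paired-biopsy variant tables with planted true somatic variants,
shared (germline-like) contaminants and strand/significance artifacts — so
every downstream stage can be scored against a truth sidecar without any
external data.

Default design scale mirrors the lineage-tracing study: sampling at 1.5, 3,
6 and 12 weeks with clone counts of 50/75/199/196 (mutant genotype) and
93/106/181/183 (wild-type reporter control) and 3 animals per timepoint;
7 mice with one irradiated and one unexposed biopsy each for the variant
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import h2b
from .params import SPParams
from .sp_model import sample_clone_sizes

__all__ = ["StudyDesign", "gen_clone_table", "gen_dilution_data", "gen_variant_table"]

#: Fig-matched clone counts per sampling time (weeks).
_DEFAULT_CLONE_COUNTS = {
    "mutant": {1.5: 50, 3.0: 75, 6.0: 199, 12.0: 196},
    "wild_type": {1.5: 93, 3.0: 106, 6.0: 181, 12.0: 183},
}


@dataclass(frozen=True)
class StudyDesign:
    """Design of a full synthetic study with known truth."""

    sampling_times: tuple[float, ...] = (1.5, 3.0, 6.0, 12.0)
    genotype_params: dict = field(
        default_factory=lambda: {
            "wild_type": SPParams(delta=0.0),
            "mutant": SPParams(delta=0.25),
        }
    )
    clones_per_timepoint: dict | int = field(
        default_factory=lambda: dict(_DEFAULT_CLONE_COUNTS)
    )
    animals_per_timepoint: int = 3
    detection_min: int = 1
    dilution: h2b.DilutionConfig = field(default_factory=h2b.DilutionConfig)
    # variant-table truth
    n_mice: int = 7
    true_per_irradiated: int = 8
    true_per_unexposed: int = 1
    shared_per_mouse: int = 5
    weak_artifacts_per_biopsy: int = 20
    single_strand_per_biopsy: int = 5
    true_ct_fraction: float = 0.75
    master_seed: int = 0

    def clone_count(self, genotype: str, t: float) -> int:
        if isinstance(self.clones_per_timepoint, int):
            return self.clones_per_timepoint
        return int(self.clones_per_timepoint[genotype][float(t)])


def gen_clone_table(
    design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate detected clones per genotype and sampling time.

    Clones are independent single-progenitor realisations started from one
    progenitor; only clones satisfying the detection rule
    (basal >= detection_min) are kept, resampling until the requested number
    of detected clones is reached.  Returns (clone table, truth dict).
    """
    seed = design.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, params in design.genotype_params.items():
        for t in design.sampling_times:
            need = design.clone_count(genotype, t)
            collected = 0
            attempts = 0
            animal_ids = [
                f"{genotype[:2]}_t{t:g}_m{i + 1}"
                for i in range(design.animals_per_timepoint)
            ]
            while collected < need:
                batch = max(2 * (need - collected), 500)
                sizes = sample_clone_sizes(
                    params, t, batch, seed=int(rng.integers(0, 2**31 - 1))
                )
                basal = sizes[:, 0] + sizes[:, 1]
                detected = sizes[basal >= design.detection_min]
                attempts += batch
                if attempts >= 10_000 and collected + len(detected) == 0:
                    raise ValueError(
                        f"detection probability < 1e-4 for {genotype} at t={t}"
                    )
                for row in detected:
                    if collected >= need:
                        break
                    rows.append(
                        {
                            "animal_id": animal_ids[collected % len(animal_ids)],
                            "genotype": genotype,
                            "time_weeks": float(t),
                            "n_basal": int(row[0] + row[1]),
                            "n_suprabasal": int(row[2]),
                        }
                    )
                    collected += 1
    table = pd.DataFrame(
        rows, columns=["animal_id", "genotype", "time_weeks", "n_basal", "n_suprabasal"]
    )
    truth = {"seed": seed, "detection_min": design.detection_min}
    for genotype, params in design.genotype_params.items():
        for key in ("r", "lam", "delta", "gamma", "mu"):
            truth[f"{genotype}_{key}"] = getattr(params, key)
    return table, truth


def gen_dilution_data(
    design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """H2BGFP chase intensities for ``animals_per_timepoint`` animals.

    Delegates to :func:`epiclone.h2b.simulate_dilution`; per-animal samples
    are independent.  Returns (intensity table, truth dict).
    """
    seed = design.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    frames = [
        h2b.simulate_dilution(
            design.dilution,
            seed=int(rng.integers(0, 2**31 - 1)),
            animal_id=f"m{i + 1}",
        )
        for i in range(design.animals_per_timepoint)
    ]
    truth = {
        "seed": seed,
        "lam": design.dilution.lam,
        "i0_log2": design.dilution.i0_log2,
        "noise_sd": design.dilution.noise_sd,
        "slow_fraction": design.dilution.slow_fraction,
        "lam_slow": design.dilution.lam_slow,
    }
    return pd.concat(frames, ignore_index=True), truth


_PYR = ["C", "T"]
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _draw_snv(rng, ct_bias: float):
    """Random SNV; with probability ct_bias a C>T (possibly strand-flipped)."""
    if rng.random() < ct_bias:
        sub = "C>T"
    else:
        sub = _SUBS[rng.integers(0, len(_SUBS))]
    ref, alt = sub.split(">")
    if rng.random() < 0.5:  # report on the purine strand
        ref, alt = _COMP[ref], _COMP[alt]
    return ref, alt


def gen_variant_table(
    design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-biopsy variant table with planted truth.

    Plants, per mouse (one irradiated and one unexposed biopsy):

    * true somatic variants unique to one biopsy, tiny p-values, balanced
      strand support, UV-like C>T-dominated spectrum — these and only these
      should survive the full filtering pipeline;
    * shared variants present in both biopsies (germline/artifact-like),
      small p-values — removed by the paired-sharing rule;
    * weak artifacts with large p-values — removed by the BH step;
    * single-strand artifacts with small p-values — removed by the strand
      filter.

    Returns (records, truth) where ``truth`` is the sub-table of records
    expected to survive, keyed by (chrom, pos, ref, alt, biopsy_id).
    """
    seed = design.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rows = []
    used_pos: set[tuple[str, int]] = set()

    def new_site():
        while True:
            chrom = f"chr{rng.integers(1, 20)}"
            pos = int(rng.integers(1, 10_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                return chrom, pos

    def record(mouse, biopsy, exposure, kind):
        chrom, pos = new_site()
        if kind == "true":
            ref, alt = _draw_snv(rng, design.true_ct_fraction)
            p = 10.0 ** rng.uniform(-12, -6)
            fwd = 1 + rng.poisson(8)
            rev = 1 + rng.poisson(8)
        elif kind == "weak":
            ref, alt = _draw_snv(rng, 0.0)
            p = rng.uniform(0.3, 1.0)
            fwd = 1 + rng.poisson(2)
            rev = 1 + rng.poisson(2)
        elif kind == "single_strand":
            ref, alt = _draw_snv(rng, 0.0)
            p = 10.0 ** rng.uniform(-10, -6)
            fwd, rev = (1 + rng.poisson(10), 0)
            if rng.random() < 0.5:
                fwd, rev = rev, fwd
        else:
            raise AssertionError(kind)
        return {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "biopsy_id": biopsy,
            "mouse_id": mouse,
            "exposure": exposure,
            "p_value": p,
            "fwd_reads": int(fwd),
            "rev_reads": int(rev),
            "planted_as": kind,
        }

    for m in range(design.n_mice):
        mouse = f"mouse{m + 1}"
        biopsies = {
            "irradiated": f"{mouse}_uv",
            "unexposed": f"{mouse}_ctl",
        }
        for exposure, n_true in (
            ("irradiated", design.true_per_irradiated),
            ("unexposed", design.true_per_unexposed),
        ):
            for _ in range(n_true):
                rows.append(record(mouse, biopsies[exposure], exposure, "true"))
            for _ in range(design.weak_artifacts_per_biopsy):
                rows.append(record(mouse, biopsies[exposure], exposure, "weak"))
            for _ in range(design.single_strand_per_biopsy):
                rows.append(
                    record(mouse, biopsies[exposure], exposure, "single_strand")
                )
        # shared variants: same site in both biopsies of this mouse
        for _ in range(design.shared_per_mouse):
            chrom, pos = new_site()
            ref, alt = _draw_snv(rng, 0.0)
            p = 10.0 ** rng.uniform(-10, -6)
            for exposure, biopsy in biopsies.items():
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "biopsy_id": biopsy,
                        "mouse_id": mouse,
                        "exposure": exposure,
                        "p_value": p,
                        "fwd_reads": int(1 + rng.poisson(8)),
                        "rev_reads": int(1 + rng.poisson(8)),
                        "planted_as": "shared",
                    }
                )

    records = pd.DataFrame(rows)
    truth = records.loc[
        records["planted_as"] == "true",
        ["chrom", "pos", "ref", "alt", "biopsy_id"],
    ].reset_index(drop=True)
    records = records.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1)))
    return records.reset_index(drop=True), truth
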