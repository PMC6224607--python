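"""Non-spatial stochastic clonal competition under ongoing mutagenesis.

A constant population of ``n_cells`` progenitors evolves by a Moran
birth-death process: division events occur at total rate ``lam * n_cells``;
the divider is chosen with probability proportional to its clone's
``count * (1 + delta)`` (fitness is the fate bias delta, commensurate with
the single-progenitor model); one uniformly chosen cell is removed so the
population stays constant.  With probability ``mut_rate`` the new daughter
founds a child clone whose delta is the parent's plus an independent draw
from the distribution of fitness effects (DFE), clipped so 1 + delta >= 0.

This emulates the experiment in which a transgenic mutant is induced at 1%
frequency among wild-type cells and the skin is then mutagenised (an
optional DMBA-like burst pre-seeds standing mutant clones at t = 0) and
chronically UV-exposed: the transgenic lineage first expands due to its
fate bias and is later displaced by fitter de-novo mutant clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "CompetitionConfig",
    "FrequencySeries",
    "run_competition",
    "transgenic_lineage_frequency",
    "muller_table",
    "summarize_runs",
    "fixation_probability_exact",
]

WILD_TYPE = 0
TRANSGENIC = 1


@dataclass(frozen=True)
class CompetitionConfig:
    """Configuration of a competition run.

    dfe_* fields describe the distribution of fitness effects of new
    mutations: with probability ``dfe_p_neutral`` the effect is 0, with
    probability ``dfe_p_deleterious`` it is -Exp(mean dfe_s_mean), otherwise
    +Exp(mean dfe_s_mean).  ``dmba_fraction`` pre-seeds that fraction of
    cells at t = 0 with one standing mutation each (single-pulse mutagen).
    """

    n_cells: int = 2000
    f0: float = 0.01
    lam: float = 1.2
    delta0: float = 0.2
    mut_rate: float = 0.005
    dfe_p_neutral: float = 0.9
    dfe_p_deleterious: float = 0.0
    dfe_s_mean: float = 0.2
    dmba_fraction: float = 0.1
    t_end: float = 52.0
    record_interval: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f0 < 1.0):
            raise ValueError("f0 must be in (0, 1)")
        if not (0.0 <= self.mut_rate <= 1.0):
            raise ValueError("mut_rate must be in [0, 1]")
        if self.n_cells * self.f0 < 1.0:
            raise ValueError("n_cells * f0 must be >= 1")
        if self.dfe_p_neutral + self.dfe_p_deleterious > 1.0:
            raise ValueError("DFE probabilities exceed 1")
        if self.t_end < 0 or self.record_interval <= 0:
            raise ValueError("t_end >= 0 and record_interval > 0 required")


@dataclass
class FrequencySeries:
    """Recorded clone counts on a regular time grid.

    ``counts[i, c]`` is the cell count of clone c at time ``t[i]``; rows sum
    to ``n_cells``.
    """

    t: np.ndarray
    counts: np.ndarray
    n_cells: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_cells


@njit(cache=True)
def _moran_kernel(
    n_cells,
    counts0,
    delta0_arr,
    is_trans0,
    lam,
    mut_rate,
    p_neutral,
    p_del,
    s_mean,
    t_end,
    record_dt,
    max_clones,
    seed,
):
    np.random.seed(seed)
    n_rec = int(np.floor(t_end / record_dt + 1e-9)) + 1
    counts = np.zeros(max_clones, dtype=np.int64)
    delta = np.zeros(max_clones, dtype=np.float64)
    parent = np.full(max_clones, -1, dtype=np.int64)
    birth = np.zeros(max_clones, dtype=np.float64)
    is_trans = np.zeros(max_clones, dtype=np.uint8)

    n0 = counts0.size
    for i in range(n0):
        counts[i] = counts0[i]
        delta[i] = delta0_arr[i]
        is_trans[i] = is_trans0[i]
    n_clones = n0
    parent[0] = -1

    rec = np.zeros((n_rec, max_clones), dtype=np.int64)
    rec_i = 0
    rec[0, :n0] = counts[:n0]
    rec_i = 1

    weight = 0.0
    for i in range(n_clones):
        weight += counts[i] * (1.0 + delta[i])

    total_rate = lam * n_cells
    t = 0.0
    n_clipped = 0
    overflow = 0
    while True:
        t += np.random.exponential(1.0 / total_rate)
        while rec_i < n_rec and t > rec_i * record_dt:
            rec[rec_i, :n_clones] = counts[:n_clones]
            rec_i += 1
        if t > t_end:
            break
        # divider: proportional to count * (1 + delta)
        u = np.random.random() * weight
        acc = 0.0
        div = n_clones - 1
        for i in range(n_clones):
            if counts[i] > 0:
                acc += counts[i] * (1.0 + delta[i])
                if acc >= u:
                    div = i
                    break
        # dying cell: uniform over all cells
        v = np.random.random() * n_cells
        acc = 0.0
        die = n_clones - 1
        for i in range(n_clones):
            if counts[i] > 0:
                acc += counts[i]
                if acc >= v:
                    die = i
                    break
        # daughter: same clone, or a new child clone upon mutation
        if np.random.random() < mut_rate:
            if n_clones >= max_clones:
                overflow = 1
                break
            w = np.random.random()
            if w < p_neutral:
                eff = 0.0
            elif w < p_neutral + p_del:
                eff = -np.random.exponential(s_mean)
            else:
                eff = np.random.exponential(s_mean)
            child_delta = delta[div] + eff
            if child_delta < -1.0:
                child_delta = -1.0
                n_clipped += 1
            c = n_clones
            counts[c] = 1
            delta[c] = child_delta
            parent[c] = div
            birth[c] = t
            is_trans[c] = is_trans[div]
            n_clones += 1
            weight += 1.0 + child_delta
        else:
            counts[div] += 1
            weight += 1.0 + delta[div]
        counts[die] -= 1
        weight -= 1.0 + delta[die]

    while rec_i < n_rec:
        rec[rec_i, :n_clones] = counts[:n_clones]
        rec_i += 1

    return rec, counts, delta, parent, birth, is_trans, n_clones, n_clipped, overflow


def run_competition(
    config: CompetitionConfig, seed: int = 0
) -> tuple[FrequencySeries, pd.DataFrame]:
    """Simulate the Moran competition; returns (series, clone registry).

    The registry has one row per clone: clone_id, parent_id (-1 for the two
    founding populations), delta, is_transgenic_lineage, birth_time.
    Reproducible: identical config + seed give identical outputs.
    """
    n = config.n_cells
    n_trans = int(round(config.f0 * n))
    rng = np.random.default_rng(seed)

    counts0 = [n - n_trans, n_trans]
    delta0_arr = [0.0, config.delta0]
    is_trans0 = [0, 1]
    # DMBA-like standing mutations: single cells split off the wild-type pool
    n_dmba = int(round(config.dmba_fraction * (n - n_trans)))
    for _ in range(n_dmba):
        w = rng.random()
        if w < config.dfe_p_neutral:
            eff = 0.0
        elif w < config.dfe_p_neutral + config.dfe_p_deleterious:
            eff = -rng.exponential(config.dfe_s_mean)
        else:
            eff = rng.exponential(config.dfe_s_mean)
        counts0[0] -= 1
        counts0.append(1)
        delta0_arr.append(max(eff, -1.0))
        is_trans0.append(0)

    expected_muts = config.lam * n * config.t_end * config.mut_rate
    max_clones = int(len(counts0) + 4 * expected_muts + 1000)

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    while True:
        (
            rec,
            counts,
            delta,
            parent,
            birth,
            is_trans,
            n_clones,
            n_clipped,
            overflow,
        ) = _moran_kernel(
            n,
            np.asarray(counts0, dtype=np.int64),
            np.asarray(delta0_arr, dtype=np.float64),
            np.asarray(is_trans0, dtype=np.uint8),
            config.lam,
            config.mut_rate,
            config.dfe_p_neutral,
            config.dfe_p_deleterious,
            config.dfe_s_mean,
            config.t_end,
            config.record_interval,
            max_clones,
            kernel_seed,
        )
        if not overflow:
            break
        max_clones *= 2

    n_rec = rec.shape[0]
    t = np.arange(n_rec) * config.record_interval
    series = FrequencySeries(t=t, counts=rec[:, :n_clones].copy(), n_cells=n)
    # parent ids for the DMBA founders point at the wild-type pool
    parent_ids = parent[:n_clones].copy()
    parent_ids[2 : len(counts0)] = WILD_TYPE
    registry = pd.DataFrame(
        {
            "clone_id": np.arange(n_clones),
            "parent_id": parent_ids,
            "delta": delta[:n_clones],
            "is_transgenic_lineage": is_trans[:n_clones].astype(bool),
            "birth_time": birth[:n_clones],
        }
    )
    registry.attrs["seed"] = seed
    registry.attrs["n_fitness_clipped"] = int(n_clipped)
    return series, registry


def transgenic_lineage_frequency(
    series: FrequencySeries, registry: pd.DataFrame
) -> np.ndarray:
    """Frequency of the transgenic clone plus all its mutant descendants."""
    if series.counts.shape[1] != len(registry):
        raise ValueError("series and registry describe different clone sets")
    known = set(registry["clone_id"])
    bad = registry.loc[
        (registry["parent_id"] >= 0) & ~registry["parent_id"].isin(known),
        "clone_id",
    ]
    if len(bad):
        raise ValueError(f"orphan parent ids for clones {list(bad)}")
    mask = registry["is_transgenic_lineage"].to_numpy()
    return series.counts[:, mask].sum(axis=1) / series.n_cells


def muller_table(
    series: FrequencySeries, registry: pd.DataFrame
) -> pd.DataFrame:
    """Long-format (time, clone_id, parent_id, frequency) table.

    Suitable for Muller-plot rendering; clone ids are in birth order so a
    parent always precedes its children.  Frequencies sum to 1 per time.
    """
    if series.counts.shape[1] != len(registry):
        raise ValueError("series and registry describe different clone sets")
    n_rec, n_clones = series.counts.shape
    out = pd.DataFrame(
        {
            "time_weeks": np.repeat(series.t, n_clones),
            "clone_id": np.tile(registry["clone_id"].to_numpy(), n_rec),
            "parent_id": np.tile(registry["parent_id"].to_numpy(), n_rec),
            "frequency": (series.counts / series.n_cells).ravel(),
        }
    )
    return out


def summarize_runs(
    results: list[tuple[FrequencySeries, pd.DataFrame]],
    rise_factor: float = 2.0,
    fall_fraction: float = 0.5,
    f0: float | None = None,
) -> pd.DataFrame:
    """Per-run peak/final statistics of the transgenic lineage.

    ``rose_then_fell`` is True when the lineage peak exceeds
    ``rise_factor * f0`` and the final frequency is below
    ``fall_fraction * peak``.
    """
    if not results:
        raise ValueError("at least one run required")
    rows = []
    for series, registry in results:
        freq = transgenic_lineage_frequency(series, registry)
        start = f0 if f0 is not None else freq[0]
        peak_i = int(np.argmax(freq))
        peak = float(freq[peak_i])
        final = float(freq[-1])
        rows.append(
            {
                "peak_frequency": peak,
                "peak_time": float(series.t[peak_i]),
                "final_frequency": final,
                "rose_then_fell": bool(
                    peak >= rise_factor * start and final <= fall_fraction * peak
                ),
            }
        )
    return pd.DataFrame(rows)


def fixation_probability_exact(
    n_cells: int, delta: float, k0: int = 1
) -> float:
    """Exact fixation probability of a clone of size k0 with fate bias delta.

    Brute-force absorbing-chain solve of the two-clone Moran birth-death
    process (divider chosen proportional to count * (1 + delta), uniform
    removal) on the (n_cells + 1)-state chain.  Independent oracle for the
    stochastic simulator.
    """
    if not (0 <= k0 <= n_cells):
        raise ValueError("k0 must be in [0, n_cells]")
    n = n_cells
    w = 1.0 + delta
    # absorbing states 0 and n; solve (I - T) h = b for interior states
    size = n - 1
    a = np.zeros((size, size))
    b = np.zeros(size)
    for k in range(1, n):
        wk = w * k + (n - k)
        p_up = (w * k / wk) * ((n - k) / n)
        p_dn = ((n - k) / wk) * (k / n)
        stay = 1.0 - p_up - p_dn
        i = k - 1
        a[i, i] = 1.0 - stay
        if k + 1 < n:
            a[i, i + 1] = -p_up
        else:
            b[i] += p_up
        if k - 1 > 0:
            a[i, i - 1] = -p_dn
    h = np.linalg.solve(a, b)
    if k0 == 0:
        return 0.0
    if k0 == n:
        return 1.0
    return float(h[k0 - 1])
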