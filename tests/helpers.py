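"""Shared numeric helpers for the test suite."""

import numpy as np
import pandas as pd


def make_clone_table(sizes_by_time: dict[float, list[int]]) -> pd.DataFrame:
    rows = []
    for t, sizes in sizes_by_time.items():
        for i, b in enumerate(sizes):
            rows.append(
                {
                    "animal_id": f"m{i % 3 + 1}",
                    "genotype": "test",
                    "time_weeks": float(t),
                    "n_basal": int(b),
                    "n_suprabasal": 0,
                }
            )
    return pd.DataFrame(rows)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    n = max(p.size, q.size)
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: p.size] = p
    qq[: q.size] = q
    return 0.5 * float(np.abs(pp - qq).sum())


def empirical_basal_pmf(sizes: np.ndarray, n_max: int) -> np.ndarray:
    basal = sizes[:, 0] + sizes[:, 1]
    return np.bincount(np.minimum(basal, n_max), minlength=n_max + 1) / basal.size
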