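"""Mean-field two-genotype tissue model of the interfollicular epidermis.

Tracks, per genotype g, densities of progenitors P_g, differentiated basal
cells D_g and suprabasal cells S_g (cells per unit basal area):

    dP_g/dt = lam_g * delta_eff_g * P_g
    dD_g/dt = lam_g * (1 - delta_eff_g) * P_g - gamma_g * D_g
    dS_g/dt = gamma_g * D_g - mu_g * S_g

``delta_eff = delta * max(0, 1 - k (B_total/B_0 - 1))`` when the optional
crowding feedback (k > 0) is enabled; B_total is total basal density.

The wild type must be homeostatic (delta = 0, gamma * D = lam * P,
mu * S = gamma * D at t = 0), so any departure of the summary series from
their initial values is attributable to the mutant perturbation.  This is
the machinery behind the mechanistic hypothesis scan: which perturbations
of mutant fate, stratification or shedding reproduce the observed pattern
of a progressively rising mutant basal fraction, a faster-rising mutant
suprabasal fraction, and epidermal thickening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import SPParams

__all__ = [
    "TissueParams",
    "TissueTrajectory",
    "simulate_mean_field",
    "thickness_proxy",
    "hypothesis_scan",
    "HYPOTHESES",
    "SIGNATURES",
]


@dataclass(frozen=True)
class TissueParams:
    """Two-genotype mean-field tissue parameters.

    ``init_mutant_fraction`` applies uniformly to all three compartments at
    t = 0 (induction labels a representative cross-section of the tissue).
    ``feedback_strength`` k >= 0 linearly attenuates the mutant fate
    imbalance as total basal density rises above its initial value; 0
    disables the feedback.
    """

    wild_type: SPParams = field(default_factory=SPParams)
    mutant: SPParams = field(default_factory=SPParams)
    init_mutant_fraction: float = 0.05
    feedback_strength: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.init_mutant_fraction <= 1.0):
            raise ValueError("init_mutant_fraction must be in [0, 1]")
        if self.feedback_strength < 0:
            raise ValueError("feedback_strength must be >= 0")
        wt = self.wild_type
        if abs(wt.delta) > 1e-12:
            raise ValueError("wild type must be homeostatic (delta = 0)")
        if wt.gamma <= 0 or wt.mu <= 0 or wt.lam <= 0:
            raise ValueError("wild-type rates must be positive for homeostasis")


@dataclass
class TissueTrajectory:
    """Solution of the mean-field model on a time grid (weeks).

    ``densities[genotype]`` is an (n_times, 3) array of (P, D, S).
    """

    t: np.ndarray
    densities: dict[str, np.ndarray]

    @property
    def basal_total(self) -> np.ndarray:
        return sum(v[:, 0] + v[:, 1] for v in self.densities.values())

    @property
    def suprabasal_total(self) -> np.ndarray:
        return sum(v[:, 2] for v in self.densities.values())

    def labeled_fraction(self, compartment: str = "basal") -> np.ndarray:
        """Mutant fraction of the basal or suprabasal compartment."""
        mut = self.densities["mutant"]
        if compartment == "basal":
            num = mut[:, 0] + mut[:, 1]
            den = self.basal_total
        elif compartment == "suprabasal":
            num = mut[:, 2]
            den = self.suprabasal_total
        else:
            raise ValueError("compartment must be 'basal' or 'suprabasal'")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_weeks, genotype, compartment, density."""
        rows = []
        comps = ("progenitor", "differentiated_basal", "suprabasal")
        for genotype, dens in self.densities.items():
            for j, comp in enumerate(comps):
                for ti, value in zip(self.t, dens[:, j]):
                    rows.append((ti, genotype, comp, value))
        return pd.DataFrame(
            rows, columns=["time_weeks", "genotype", "compartment", "density"]
        )


def _homeostatic_point(p: SPParams, basal_density: float) -> np.ndarray:
    """(P, D, S) steady state with total basal density ``basal_density``."""
    # gamma D = lam P  and  mu S = gamma D
    d_over_p = p.lam / p.gamma
    prog = basal_density / (1.0 + d_over_p)
    diff = basal_density - prog
    supra = p.gamma * diff / p.mu
    return np.array([prog, diff, supra])


def simulate_mean_field(
    params: TissueParams,
    t_grid: np.ndarray,
    basal_density: float = 1.0,
) -> TissueTrajectory:
    """Integrate the mean-field compartment ODEs on ``t_grid`` (weeks).

    The tissue starts at the wild-type homeostatic point with the mutant
    occupying ``init_mutant_fraction`` of every compartment.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")

    steady = _homeostatic_point(params.wild_type, basal_density)
    f0 = params.init_mutant_fraction
    y0 = np.concatenate([(1.0 - f0) * steady, f0 * steady])
    b0 = steady[0] + steady[1]
    k = params.feedback_strength
    genos = (params.wild_type, params.mutant)

    def rhs(_t, y):
        dy = np.empty(6)
        b_total = y[0] + y[1] + y[3] + y[4]
        atten = max(0.0, 1.0 - k * (b_total / b0 - 1.0)) if k > 0 else 1.0
        for i, g in enumerate(genos):
            prog, diff, supra = y[3 * i : 3 * i + 3]
            d_eff = g.delta * atten
            dy[3 * i] = g.lam * d_eff * prog
            dy[3 * i + 1] = g.lam * (1.0 - d_eff) * prog - g.gamma * diff
            dy[3 * i + 2] = g.gamma * diff - g.mu * supra
        return dy

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)
    return TissueTrajectory(
        t=t_grid,
        densities={"wild_type": y[:, :3], "mutant": y[:, 3:]},
    )


def thickness_proxy(traj: TissueTrajectory) -> np.ndarray:
    """Dimensionless layer-count proxy for epidermal thickness.

    1 + suprabasal/basal density ratio; constant for a homeostatic tissue.
    The mapping to micrometres is out of scope.
    """
    return 1.0 + traj.suprabasal_total / traj.basal_total


# ---------------------------------------------------------------------------
# Hypothesis scan
# ---------------------------------------------------------------------------

#: Candidate mechanistic perturbations of the mutant genotype, applied to a
#: homeostatic baseline.  Magnitudes are model defaults (see docs/methods.md):
#: fate imbalance delta = 0.2, 5-fold stratification slow-down, 10-fold
#: (substantial) shedding slow-down, doubling of the symmetric-division
#: proportion.
HYPOTHESES = {
    "symmetric_proportion_change": {"r": 0.5},
    "stratification_decrease": {"gamma_factor": 0.2},
    "shedding_decrease": {"mu_factor": 0.1},
    "fate_imbalance": {"delta": 0.2},
    "imbalance_plus_shedding": {"delta": 0.2, "mu_factor": 0.1},
}

#: Qualitative empirical signatures, evaluated on a 12-week trajectory.
SIGNATURES = ("basal_rise", "suprabasal_faster", "thickness_increase")


def _apply_hypothesis(base: SPParams, spec: dict) -> SPParams:
    p = base
    if "r" in spec:
        p = p.with_(r=spec["r"])
    if "delta" in spec:
        p = p.with_(delta=spec["delta"])
    if "gamma_factor" in spec:
        p = p.with_(gamma=p.gamma * spec["gamma_factor"])
    if "mu_factor" in spec:
        p = p.with_(mu=p.mu * spec["mu_factor"])
    return p


def evaluate_signatures(
    traj: TissueTrajectory,
    t_check: float = 12.0,
    basal_rise_fold: float = 2.0,
    progressive_fold: float = 1.25,
    suprabasal_ratio: float = 1.2,
    thickness_fold: float = 1.1,
) -> dict[str, bool]:
    """Explicit inequality tests for the three empirical signatures.

    basal_rise
        mutant basal fraction at ``t_check`` at least ``basal_rise_fold``
        times its initial value AND still rising progressively (at least
        ``progressive_fold`` growth over the second half of the window) —
        i.e. not a transient that has already saturated.
    suprabasal_faster
        fold-rise of the mutant suprabasal fraction exceeds
        ``suprabasal_ratio`` times the fold-rise of the basal fraction.
    thickness_increase
        thickness proxy at ``t_check`` at least ``thickness_fold`` times
        its initial value.
    """
    t = traj.t
    i_end = int(np.argmin(np.abs(t - t_check)))
    i_mid = int(np.argmin(np.abs(t - t_check / 2.0)))
    fb = traj.labeled_fraction("basal")
    fs = traj.labeled_fraction("suprabasal")
    thick = thickness_proxy(traj)

    if fb[0] <= 0:
        return {name: False for name in SIGNATURES}
    basal_fold = fb[i_end] / fb[0]
    basal_rise = (
        basal_fold >= basal_rise_fold
        and fb[i_end] >= progressive_fold * fb[i_mid]
    )
    supra_fold = fs[i_end] / fs[0]
    suprabasal_faster = supra_fold >= suprabasal_ratio * basal_fold
    thickness_increase = thick[i_end] >= thickness_fold * thick[0]
    return {
        "basal_rise": bool(basal_rise),
        "suprabasal_faster": bool(suprabasal_faster),
        "thickness_increase": bool(thickness_increase),
    }


def hypothesis_scan(
    base: TissueParams | None = None,
    hypotheses: dict[str, dict] | None = None,
    t_check: float = 12.0,
    n_steps: int = 241,
) -> pd.DataFrame:
    """Deterministic boolean table: hypothesis x signature.

    Each named hypothesis perturbs the mutant genotype of a homeostatic
    baseline tissue and the trajectory is tested against the three
    signatures.  Unknown hypothesis names raise with the valid list.
    """
    if base is None:
        base = TissueParams()
    if hypotheses is None:
        hypotheses = HYPOTHESES
    unknown = [h for h in hypotheses if h not in HYPOTHESES]
    if unknown and hypotheses is not HYPOTHESES:
        # user-supplied dicts may define new perturbations; only names that
        # look like references to the canonical set are checked
        for h in unknown:
            if not isinstance(hypotheses[h], dict):
                raise ValueError(
                    f"unknown hypothesis {h!r}; valid: {sorted(HYPOTHESES)}"
                )
    t_grid = np.linspace(0.0, t_check, n_steps)
    rows = []
    for name, spec in hypotheses.items():
        if isinstance(spec, str):
            raise ValueError(
                f"unknown hypothesis {spec!r}; valid: {sorted(HYPOTHESES)}"
            )
        mut = _apply_hypothesis(base.wild_type, spec)
        params = replace(base, mutant=mut)
        traj = simulate_mean_field(params, t_grid)
        sig = evaluate_signatures(traj, t_check=t_check)
        rows.append({"hypothesis": name, **sig, "passes_all": all(sig.values())})
    return pd.DataFrame(rows)
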