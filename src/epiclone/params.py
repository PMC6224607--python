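"""Parameters of the single-progenitor model of interfollicular epidermis.

The model describes a homeostatic basal layer maintained by a single
population of progenitor cells (P) with stochastic division outcomes.  On
division a progenitor produces two progenitors (PP), two post-mitotic
differentiated basal cells (DD) or one of each (PD).  Differentiated basal
cells (D) stratify into the suprabasal compartment (S) at rate ``gamma`` and
suprabasal cells are shed at rate ``mu``.

The balanced model has P(PP) = P(DD) = r.  Fate imbalance is measured by
``delta`` = P(PP) - P(DD); the symmetric split

    p_PP = r + delta/2,   p_DD = r - delta/2,   p_PD = 1 - 2 r

makes ``delta = 0`` exactly the balanced model while keeping the total
symmetric-division proportion 2r fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["SPParams", "read_params", "write_params"]

_PARAM_KEYS = ("r", "lam", "delta", "gamma", "mu")


@dataclass(frozen=True)
class SPParams:
    """Rates and fate probabilities of the single-progenitor process.

    Parameters
    ----------
    r : float
        Probability of a symmetric PP (or DD) division in the balanced
        model, in (0, 0.5].
    lam : float
        Progenitor division rate, events per week, > 0 (0 allowed for
        degenerate test cases).
    delta : float
        Fate imbalance P(PP) - P(DD); 0 is homeostasis.
    gamma : float
        Stratification rate of differentiated basal cells, per week, >= 0.
    mu : float
        Shedding rate of suprabasal cells, per week, >= 0.
    """

    r: float = 0.25
    lam: float = 1.2
    delta: float = 0.0
    gamma: float = 1.2
    mu: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.r <= 0.5):
            raise ValueError(f"r must be in (0, 0.5], got {self.r}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.gamma < 0 or self.mu < 0:
            raise ValueError("gamma and mu must be >= 0")
        for name, p in zip(("p_PP", "p_DD", "p_PD"), self.fate_probs):
            if not (0.0 <= p <= 1.0 + 1e-12):
                raise ValueError(
                    f"fate probability {name}={p:.4g} outside [0, 1] "
                    f"(r={self.r}, delta={self.delta})"
                )

    @property
    def p_pp(self) -> float:
        return self.r + self.delta / 2.0

    @property
    def p_dd(self) -> float:
        return self.r - self.delta / 2.0

    @property
    def p_pd(self) -> float:
        return 1.0 - 2.0 * self.r

    @property
    def fate_probs(self) -> tuple[float, float, float]:
        """(p_PP, p_DD, p_PD); always sums to 1."""
        return (self.p_pp, self.p_dd, self.p_pd)

    def with_(self, **kwargs) -> "SPParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def in_days(self) -> "SPParams":
        """Explicit unit conversion: rates per day instead of per week."""
        return replace(
            self, lam=self.lam / 7.0, gamma=self.gamma / 7.0, mu=self.mu / 7.0
        )


def write_params(params: SPParams, path) -> None:
    """Write parameters as a flat key-value config file (keys r, lam, delta, gamma, mu)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# single-progenitor parameters (rates per week)\n")
        for key in _PARAM_KEYS:
            fh.write(f"{key} = {getattr(params, key)!r}\n")


def read_params(path) -> SPParams:
    """Read parameters from a flat key-value config file."""
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _PARAM_KEYS:
                raise ValueError(f"unknown parameter key {key!r} in {path}")
            values[key] = float(raw.strip())
    missing = [k for k in _PARAM_KEYS if k not in values]
    if missing:
        raise ValueError(f"missing parameter keys {missing} in {path}")
    return SPParams(**values)
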