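"""Domain types for the nine-state pre-breeding-census life cycle.

Classes (census at the start of each breeding season):

====  =====  ==============================================
index  name  meaning
====  =====  ==============================================
0      Y     yearlings (age 1)
1      P2    pre-breeders of age 2
2      P3    pre-breeders of age 3
3      P4    pre-breeders of age 4
4      P5    pre-breeders of age 5
5      P6    pre-breeders of age 6
6      F     first-time breeders (locals + immigrants)
7      E     experienced breeders
8      S     skippers (bred before, no nest this year)
====  =====  ==============================================

Demographic rates are indexed by the year in which the interval starts:
``phi2[t]`` is survival over ``(t, t+1]``, ``psi_b[t]`` the probability that
a breeder at ``t`` breeds again at ``t+1`` given survival, and so on.  The
per-capita fledging rates ``pi_f[t]`` / ``pi_e[t]`` apply to the breeding
season of year ``t`` (half the number of fledglings per nest, since a nest
has two adults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np

CLASSES = ("Y", "P2", "P3", "P4", "P5", "P6", "F", "E", "S")
N_CLASSES = len(CLASSES)
Y, P2, P3, P4, P5, P6, F, E, S = range(N_CLASSES)

_PROB_FIELDS = ("phi0", "phi2", "rho3", "rho4", "rho5", "rho6", "psi_b", "psi_s")
_RATE_FIELDS = _PROB_FIELDS + ("pi_f", "pi_e")


def _as_series(value, T: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(T, float(arr))
    if arr.shape != (T,):
        raise ValueError(f"{name} must be scalar or length-{T}, got shape {arr.shape}")
    return arr


@dataclass
class DemographicRates:
    """Annual demographic rates over a study horizon of ``T`` years.

    Recruitment is possible at ages 3-7 only; the rate at age 7 is fixed to 1
    (a pre-breeder of age 6 that survives always recruits) and is therefore
    not stored.  Scalars broadcast to constant series.
    """

    T: int
    phi0: np.ndarray
    phi2: np.ndarray
    rho3: np.ndarray
    rho4: np.ndarray
    rho5: np.ndarray
    rho6: np.ndarray
    psi_b: np.ndarray
    psi_s: np.ndarray
    pi_f: np.ndarray
    pi_e: np.ndarray

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("study horizon T must be >= 2")
        for f_ in fields(self):
            if f_.name == "T":
                continue
            setattr(self, f_.name, _as_series(getattr(self, f_.name), self.T, f_.name))
        self.validate()

    def validate(self) -> None:
        for name in _PROB_FIELDS:
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("pi_f", "pi_e"):
            arr = getattr(self, name)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def constant(cls, T: int, **values: float) -> "DemographicRates":
        return cls(T=T, **{k: values[k] for k in _RATE_FIELDS})

    def at(self, t: int) -> "RateSlice":
        """Rates governing the transition from year ``t`` to ``t+1``."""
        if not 0 <= t < self.T:
            raise ValueError(f"year index {t} outside [0, {self.T})")
        return RateSlice(**{name: float(getattr(self, name)[t]) for name in _RATE_FIELDS})

    def rho_matrix(self) -> np.ndarray:
        """(4, T) array of recruitment rates at ages 3..6."""
        return np.stack([self.rho3, self.rho4, self.rho5, self.rho6])


@dataclass(frozen=True)
class RateSlice:
    """Rates for a single annual transition."""

    phi0: float
    phi2: float
    rho3: float
    rho4: float
    rho5: float
    rho6: float
    psi_b: float
    psi_s: float
    pi_f: float
    pi_e: float

    def validate(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("pi_f", "pi_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rho(self) -> np.ndarray:
        return np.array([self.rho3, self.rho4, self.rho5, self.rho6])


@dataclass
class PopulationState:
    """Latent integer counts per year in the nine life-history classes.

    ``counts`` has shape (T, 9).  ``B[t] = F[t] + E[t]`` is the derived
    number of breeders.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[None, :]
        if self.counts.shape[-1] != N_CLASSES:
            raise ValueError(f"counts must have {N_CLASSES} columns")
        if np.any(self.counts < 0):
            raise ValueError("class counts must be non-negative")

    @property
    def T(self) -> int:
        return self.counts.shape[0]

    @property
    def breeders(self) -> np.ndarray:
        return self.counts[:, F] + self.counts[:, E]

    @property
    def nonbreeders(self) -> np.ndarray:
        return self.counts[:, :P6 + 1].sum(axis=1) + self.counts[:, S]

    def __getitem__(self, t):
        return self.counts[t]


@dataclass
class ObservationModel:
    """Detection and count-error parameters.

    ``sigma_obs`` is the SD of the log-scale breeder-count error.  Yearlings
    and older pre-breeders have year-specific resighting probabilities
    (``p_Y``, ``p_P``); breeders and skippers share one constant resighting
    probability ``p_R`` (detection is near-certain once recruited).  Status
    is never mis-assigned at resighting.
    """

    T: int
    sigma_obs: float
    p_Y: np.ndarray
    p_P: np.ndarray
    p_R: float

    def __post_init__(self):
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be > 0")
        self.p_Y = _as_series(self.p_Y, self.T, "p_Y")
        self.p_P = _as_series(self.p_P, self.T, "p_P")
        for name, arr in (("p_Y", self.p_Y), ("p_P", self.p_P)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.p_R <= 1.0:
            raise ValueError("p_R must lie in [0, 1]")


# Observation codes shared by the CSV schema and the HMM emission model.
CODE_NOT_SEEN = 0
CODE_PREBREEDER = 1
CODE_BREEDER = 2
CODE_SKIPPER = 3
CODE_NAMES: Mapping[int, str] = {
    CODE_NOT_SEEN: "not_seen",
    CODE_PREBREEDER: "pre_breeder",
    CODE_BREEDER: "breeder",
    CODE_SKIPPER: "skipper",
}
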