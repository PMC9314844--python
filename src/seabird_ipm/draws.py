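"""Container for posterior draws of parameters, latent states and flows."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# latent summaries kept per draw (beyond the raw class counts)
LATENT_KEYS = (
    "N",            # (T, 9) class counts
    "Flocal",       # (T,) local first-time breeders
    "I",            # (T,) continuous immigrant numbers
    "Ic",           # (T,) realized immigrant inflow
    "bE_FE",        # (T-1,) former breeders (from F or E) breeding at t+1
    "bS_FE",        # (T-1,) former breeders skipping at t+1
    "bE_S",         # (T-1,) former skippers breeding at t+1
    "bS_S",         # (T-1,) former skippers skipping at t+1
    "adult_survivors",  # (T-1,) survivors among age-2+ classes
)


@dataclass
class PosteriorDraws:
    """Joint posterior samples indexed (chain, draw).

    ``params`` maps a parameter name to an array of shape (chains, draws)
    for time-constant parameters or (chains, draws, T) for time-varying
    ones.  ``latent`` holds the latent-state summaries listed in
    ``LATENT_KEYS``.  All derived series are computed per draw, never from
    posterior means.
    """

    params: dict[str, np.ndarray]
    latent: dict[str, np.ndarray]
    T: int
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    def flat_param(self, name: str) -> np.ndarray:
        """(n_total,) or (n_total, T) array with chains stacked."""
        a = self.params[name]
        return a.reshape(self.n_total, *a.shape[2:])

    def flat_latent(self, name: str) -> np.ndarray:
        a = self.latent[name]
        return a.reshape(self.n_total, *a.shape[2:])

    def param_series(self, name: str) -> np.ndarray:
        """(n_total, T) series for a parameter, broadcasting constants."""
        a = self.flat_param(name)
        if a.ndim == 1:
            a = np.repeat(a[:, None], self.T, axis=1)
        return a

    @property
    def breeders(self) -> np.ndarray:
        """(n_total, T) latent number of breeders per draw."""
        N = self.flat_latent("N")
        return N[:, :, 6] + N[:, :, 7]

    # --- persistence (plain columnar text) -------------------------------
    def to_frame(self) -> pd.DataFrame:
        n_c, n_d = self.n_chains, self.n_draws
        cols = {"chain": np.repeat(np.arange(n_c), n_d),
                "draw": np.tile(np.arange(n_d), n_c)}
        for name, a in self.params.items():
            flat = a.reshape(n_c * n_d, -1)
            if flat.shape[1] == 1:
                cols[name] = flat[:, 0]
            else:
                for j in range(flat.shape[1]):
                    cols[f"{name}[{j}]"] = flat[:, j]
        for name, a in self.latent.items():
            flat = a.reshape(n_c * n_d, -1)
            shape = a.shape[2:]
            for j in range(flat.shape[1]):
                idx = np.unravel_index(j, shape)
                tag = ",".join(str(k) for k in idx)
                cols[f"{name}[{tag}]"] = flat[:, j]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, T: int, meta: dict | None = None) -> "PosteriorDraws":
        n_c = int(df["chain"].max()) + 1
        n_d = int(df["draw"].max()) + 1
        df = df.sort_values(["chain", "draw"])
        params: dict[str, np.ndarray] = {}
        latent: dict[str, dict[tuple, np.ndarray]] = {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            if "[" not in col:
                params[col] = df[col].to_numpy().reshape(n_c, n_d)
                continue
            name, idx_s = col[:-1].split("[")
            idx = tuple(int(x) for x in idx_s.split(","))
            target = latent if name in LATENT_KEYS else params
            target.setdefault(name, {})[idx] = df[col].to_numpy()
        def assemble(d):
            out = {}
            for name, parts in d.items():
                if isinstance(parts, np.ndarray):
                    out[name] = parts
                    continue
                shape = tuple(max(i[k] for i in parts) + 1 for k in range(len(next(iter(parts)))))
                arr = np.zeros((n_c * n_d, *shape))
                for idx, vals in parts.items():
                    arr[(slice(None), *idx)] = vals
                out[name] = arr.reshape(n_c, n_d, *shape)
            return out
        lat = assemble(latent)
        if "N" in lat:
            lat["N"] = lat["N"]
        return cls(params=assemble(params), latent=lat, T=T, meta=meta or {})
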