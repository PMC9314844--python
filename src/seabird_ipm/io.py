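"""File formats and the study bundle.

All tabular formats are plain CSV with a one-line header, preceded by a
``#`` comment line naming the config hash and seed that produced the file.
Capture histories are stored long-form (id, ring_year, year, code) with
codes {0 not seen, 1 pre-breeder, 2 breeder, 3 skipper}; only seen years
need a row (one code-0 row marks a never-resighted bird).  Years may carry
calendar labels; internally they are mapped to a contiguous 0-based window.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .likelihoods import HistoryMatrix, histories_from_frame
from .model import CODE_NOT_SEEN
from .synthetic import Study, SyntheticConfig


class BundleValidationError(ValueError):
    """Typed validation failure with file/context information."""

    def __init__(self, code: str, message: str):
        super().__init__(f"[{code}] {message}")
        self.code = code


@dataclass
class StudyBundle:
    """Validated in-memory study: the three IPM streams plus the optional
    patch table, on a common contiguous year window of length T."""

    counts: pd.DataFrame | None
    histories: HistoryMatrix | None
    histories_frame: pd.DataFrame | None
    reproduction: pd.DataFrame | None
    patches: pd.DataFrame | None
    T: int
    year0: int = 0
    meta: dict = field(default_factory=dict)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha={meta.get('config_sha', 'none')} seed={meta.get('seed', 'none')}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_bundle(study: Study, out_dir: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a synthetic study to a bundle directory (four CSVs, a truth
    record and a metadata file)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = asdict(study.config)
    meta = {
        "config_sha": config_hash(cfg),
        "seed": study.config.seed,
        "T": study.config.T,
        "year0": 0,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **(extra_meta or {}),
    }
    _write_csv(study.counts, out / "counts.csv", meta)
    _write_csv(study.histories, out / "histories.csv", meta)
    _write_csv(study.reproduction, out / "reproduction.csv", meta)
    _write_csv(study.patches, out / "patches.csv", meta)
    truth = {k: v for k, v in study.truth.items()
             if k not in ("trajectory", "observation_model")}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)
    with open(out / "metadata.json", "w") as fh:
        json.dump({**meta, "config": cfg}, fh, indent=1)
    return out


def _require_columns(df: pd.DataFrame, cols: set[str], name: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise BundleValidationError("missing-column", f"{name}: missing {sorted(missing)}")


def read_bundle(path: str | Path, validate: bool = True) -> StudyBundle:
    """Load and validate a bundle directory.

    Violations raise :class:`BundleValidationError` with a machine-readable
    code: missing-column, non-contiguous-years, illegal-code,
    premature-recruitment, resight-before-ringing, inconsistent-years.
    """
    p = Path(path)
    counts = _read_csv(p / "counts.csv") if (p / "counts.csv").exists() else None
    hist = _read_csv(p / "histories.csv") if (p / "histories.csv").exists() else None
    rep = _read_csv(p / "reproduction.csv") if (p / "reproduction.csv").exists() else None
    patches = _read_csv(p / "patches.csv") if (p / "patches.csv").exists() else None
    meta = {}
    if (p / "metadata.json").exists():
        meta = json.loads((p / "metadata.json").read_text())

    years = []
    if counts is not None:
        _require_columns(counts, {"year", "count"}, "counts.csv")
        years.append(counts["year"])
    if hist is not None:
        _require_columns(hist, {"id", "ring_year", "year", "code"}, "histories.csv")
        years.append(hist["year"])
    if rep is not None:
        _require_columns(rep, {"year", "category", "n_nests", "n_fledglings"}, "reproduction.csv")
        years.append(rep["year"])
    if patches is not None:
        _require_columns(patches, {"year", "patch", "n_nests", "n_fledglings"}, "patches.csv")
    if not years:
        raise BundleValidationError("missing-column", f"no data files found under {p}")

    all_years = pd.concat(years).astype(int)
    year0 = int(all_years.min())
    year_last = int(all_years.max())
    T = year_last - year0 + 1
    if counts is not None:
        cy = np.sort(counts["year"].astype(int).unique())
        if not np.array_equal(cy, np.arange(cy.min(), cy.max() + 1)):
            raise BundleValidationError("non-contiguous-years", "count series has gaps")

    def shift_years(df, cols=("year",)):
        df = df.copy()
        for col in cols:
            df[col] = df[col].astype(int) - year0
        return df

    counts_i = shift_years(counts) if counts is not None else None
    rep_i = shift_years(rep) if rep is not None else None
    patches_i = shift_years(patches) if patches is not None else None
    hist_i = shift_years(hist, ("year", "ring_year")) if hist is not None else None

    hm = None
    if hist_i is not None:
        if validate:
            bad = hist_i[(hist_i["code"] < 0) | (hist_i["code"] > 3)]
            if len(bad):
                raise BundleValidationError(
                    "illegal-code", f"histories.csv: illegal status code for id(s) "
                    f"{bad['id'].unique()[:5].tolist()}")
        try:
            hm = histories_from_frame(hist_i, T, validate=validate)
        except ValueError as exc:
            msg = str(exc)
            code = ("premature-recruitment" if "age 3" in msg
                    else "resight-before-ringing" if "ringing" in msg
                    else "invalid-history")
            raise BundleValidationError(code, f"histories.csv: {msg}") from exc

    if validate and rep_i is not None:
        bad = rep_i[(rep_i["n_nests"] == 0) & (rep_i["n_fledglings"] > 0)]
        if len(bad):
            raise BundleValidationError(
                "inconsistent-years", "reproduction.csv: fledglings recorded with zero nests")

    return StudyBundle(
        counts=counts_i, histories=hm, histories_frame=hist_i,
        reproduction=rep_i, patches=patches_i, T=T, year0=year0, meta=meta,
    )


def bundle_from_study(study: Study) -> StudyBundle:
    """In-memory bundle from a synthetic study (no files touched)."""
    hm = histories_from_frame(study.histories, study.config.T) \
        if len(study.histories) else HistoryMatrix(
            codes=np.zeros((0, study.config.T), dtype=np.int8),
            first_year=np.zeros(0, dtype=np.int64),
            first_state=np.zeros(0, dtype=np.int64),
            weights=np.zeros(0))
    return StudyBundle(
        counts=study.counts, histories=hm, histories_frame=study.histories,
        reproduction=study.reproduction, patches=study.patches,
        T=study.config.T, year0=0,
        meta={"seed": study.config.seed, "config_sha": config_hash(asdict(study.config))},
    )


# ---------------------------------------------------------------------------
# configs and posterior draws
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def write_draws(draws, out_dir: str | Path, meta: dict | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = {**draws.meta, **(meta or {})}
    _write_csv(draws.to_frame(), out / "draws.csv",
               {"config_sha": m.get("config_sha", "none"), "seed": m.get("seed", "none")})
    with open(out / "draws_meta.json", "w") as fh:
        json.dump({"T": draws.T, **{k: v for k, v in m.items() if k != "accept"}}, fh, indent=1)
    return out


def read_draws(path: str | Path):
    from .draws import PosteriorDraws
    p = Path(path)
    meta = json.loads((p / "draws_meta.json").read_text())
    df = _read_csv(p / "draws.csv")
    return PosteriorDraws.from_frame(df, T=int(meta["T"]), meta=meta)
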