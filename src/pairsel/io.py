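"""Reading and writing paired designs and chains; peak-level summaries.

A *paired design* is an n x p table of (intensity, shape) predictor pairs
plus a binary case/control outcome.  The native on-disk layout is a wide CSV
with header ``y,u_<id>,v_<id>,...``; a long (tidy) layout with columns
``sample_id,y,pair_id,u,v`` is also accepted.  Chains are persisted as JSON
lines: a header record followed by one record per stored sample, with model
configurations as sparse index lists and coefficients at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (Chain, ChainSample, ChainSettings, CoefficientState,
                    ModelConfiguration, PriorSpec)

__all__ = [
    "PeakCluster",
    "PairedDesign",
    "compute_pair_summary",
    "read_paired_table",
    "write_paired_table",
    "peaks_to_design",
    "persist_chain",
    "load_chain",
    "ChainFormatError",
]

_CHAIN_FORMAT = "pairsel-chain"
_CHAIN_VERSION = 1


class ChainFormatError(ValueError):
    """Raised when a persisted chain file cannot be parsed."""


@dataclass(frozen=True)
class PeakCluster:
    """One isotope cluster: J peaks with log intensities l_j and residuals x_j.

    The residuals measure the deviation of the observed isotopic pattern from
    the typical pattern; their construction happens upstream and they are
    accepted here as given.
    """

    cluster_id: int | str
    log_intensities: tuple[float, ...]
    residuals: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_intensities",
                           tuple(float(x) for x in self.log_intensities))
        object.__setattr__(self, "residuals",
                           tuple(float(x) for x in self.residuals))
        if len(self.log_intensities) != len(self.residuals):
            raise ValueError(
                f"cluster {self.cluster_id}: log_intensities and residuals "
                "must have equal length")
        if len(self.log_intensities) < 1:
            raise ValueError(f"cluster {self.cluster_id}: needs at least one peak")

    @property
    def J(self) -> int:
        return len(self.log_intensities)


def compute_pair_summary(cluster: PeakCluster) -> tuple[float, float]:
    """Intensity and shape summary (u, v) of one isotope cluster.

    u is the sum of the log-transformed peak intensities.  v is the center of
    gravity of the residual distribution over the peak positions 1..J:
    v = sum_j j * p_j with p_j = x_j / sum_j x_j.  When all residuals are
    non-negative, v lies in [1, J].
    """
    u = float(sum(cluster.log_intensities))
    xsum = float(sum(cluster.residuals))
    if xsum == 0.0:
        raise ValueError(
            f"shape undefined for cluster {cluster.cluster_id}: residuals sum to zero")
    j = np.arange(1, cluster.J + 1)
    v = float(j @ np.asarray(cluster.residuals) / xsum)
    return u, v


@dataclass
class PairedDesign:
    """n individuals x p (intensity, shape) pairs plus binary outcome."""

    y: np.ndarray
    U: np.ndarray
    V: np.ndarray
    pair_ids: tuple = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.shape != self.U.shape:
            raise ValueError("U and V must be equal-shape n x p matrices")
        if self.y.shape != (self.U.shape[0],):
            raise ValueError("y length must equal the number of rows of U")
        yv = np.unique(self.y)
        if not np.isin(yv, [0, 1]).all():
            raise ValueError(f"outcome must be binary 0/1; found values {yv.tolist()}")
        self.y = self.y.astype(int)
        if np.isnan(self.U).any() or np.isnan(self.V).any():
            raise ValueError("missing values in the design are not allowed")
        if not self.pair_ids:
            self.pair_ids = tuple(range(1, self.U.shape[1] + 1))
        self.pair_ids = tuple(self.pair_ids)
        if len(self.pair_ids) != self.U.shape[1]:
            raise ValueError("pair_ids length must equal p")
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("pair_ids must be unique")

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def p(self) -> int:
        return self.U.shape[1]

    def subset(self, rows) -> "PairedDesign":
        rows = np.asarray(rows)
        return PairedDesign(self.y[rows], self.U[rows], self.V[rows],
                           self.pair_ids)


def _design_from_wide(df: pd.DataFrame) -> PairedDesign:
    if "y" not in df.columns:
        raise ValueError("wide paired table must contain a 'y' column")
    u_ids = [c[2:] for c in df.columns if c.startswith("u_")]
    v_ids = [c[2:] for c in df.columns if c.startswith("v_")]
    extra = [c for c in df.columns
             if c != "y" and not (c.startswith("u_") or c.startswith("v_"))]
    if extra:
        raise ValueError(f"unrecognized columns: {extra}")
    missing_v = [i for i in u_ids if i not in set(v_ids)]
    missing_u = [i for i in v_ids if i not in set(u_ids)]
    if missing_v or missing_u:
        raise ValueError(
            "unpaired component: "
            + ", ".join([f"u_{i} has no v_{i}" for i in missing_v]
                        + [f"v_{i} has no u_{i}" for i in missing_u]))
    if df.isna().any().any():
        raise ValueError("missing values in the paired table are not allowed")
    ids = u_ids  # preserve file column order of the u columns
    U = df[[f"u_{i}" for i in ids]].to_numpy(dtype=float)
    V = df[[f"v_{i}" for i in ids]].to_numpy(dtype=float)
    return PairedDesign(df["y"].to_numpy(), U, V, tuple(ids))


def _design_from_long(df: pd.DataFrame) -> PairedDesign:
    need = {"sample_id", "y", "pair_id", "u", "v"}
    if not need <= set(df.columns):
        raise ValueError(f"long paired table requires columns {sorted(need)}")
    if df[list(need)].isna().any().any():
        raise ValueError("missing values in the paired table are not allowed")
    ycheck = df.groupby("sample_id")["y"].nunique()
    if (ycheck > 1).any():
        raise ValueError("inconsistent outcome for a sample_id in long table")
    samples = df["sample_id"].drop_duplicates().tolist()  # row order preserved
    pairs = df["pair_id"].drop_duplicates().tolist()
    wide_u = df.pivot(index="sample_id", columns="pair_id", values="u")
    wide_v = df.pivot(index="sample_id", columns="pair_id", values="v")
    wide_u = wide_u.loc[samples, pairs]
    wide_v = wide_v.loc[samples, pairs]
    if wide_u.isna().any().any() or wide_v.isna().any().any():
        raise ValueError("long table is not a complete sample x pair grid")
    y = df.drop_duplicates("sample_id").set_index("sample_id").loc[samples, "y"]
    return PairedDesign(y.to_numpy(), wide_u.to_numpy(dtype=float),
                       wide_v.to_numpy(dtype=float),
                       tuple(str(pid) for pid in pairs))


def read_paired_table(path, layout: str = "wide") -> PairedDesign:
    """Read a paired design from CSV.  ``layout`` is 'wide' or 'long'."""
    df = pd.read_csv(path)
    if layout == "wide":
        return _design_from_wide(df)
    if layout == "long":
        return _design_from_long(df)
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_paired_table(design: PairedDesign, path) -> None:
    cols = {"y": design.y}
    for j, pid in enumerate(design.pair_ids):
        cols[f"u_{pid}"] = design.U[:, j]
        cols[f"v_{pid}"] = design.V[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def peaks_to_design(peaks: pd.DataFrame, outcomes: pd.DataFrame) -> PairedDesign:
    """Build a paired design from peak-level input.

    ``peaks`` has columns sample_id, cluster_id, log_intensity, residual, one
    row per peak (peak order within a cluster is the row order).  ``outcomes``
    has columns sample_id, y.  Each (sample, cluster) group is summarized via
    compute_pair_summary.
    """
    need = {"sample_id", "cluster_id", "log_intensity", "residual"}
    if not need <= set(peaks.columns):
        raise ValueError(f"peaks table requires columns {sorted(need)}")
    if not {"sample_id", "y"} <= set(outcomes.columns):
        raise ValueError("outcomes table requires columns sample_id, y")
    samples = outcomes["sample_id"].tolist()
    clusters = peaks["cluster_id"].drop_duplicates().tolist()
    U = np.empty((len(samples), len(clusters)))
    V = np.empty_like(U)
    grouped = peaks.groupby(["sample_id", "cluster_id"], sort=False)
    for i, sid in enumerate(samples):
        for j, cid in enumerate(clusters):
            try:
                g = grouped.get_group((sid, cid))
            except KeyError:
                raise ValueError(f"sample {sid} has no peaks for cluster {cid}")
            cl = PeakCluster(cid, tuple(g["log_intensity"]), tuple(g["residual"]))
            U[i, j], V[i, j] = compute_pair_summary(cl)
    return PairedDesign(outcomes["y"].to_numpy(), U, V,
                       tuple(str(c) for c in clusters))


# ---------------------------------------------------------------------------
# Chain persistence (JSON lines)
# ---------------------------------------------------------------------------

def persist_chain(chain: Chain, path) -> None:
    """Write a chain to a JSON-lines file (header record + one per sample)."""
    if len(chain) == 0:
        raise ValueError("refusing to persist an empty chain")
    header = {
        "format": _CHAIN_FORMAT,
        "version": _CHAIN_VERSION,
        "p": chain.p,
        "pair_ids": list(chain.pair_ids),
        "settings": chain.settings.to_dict(),
        "prior": chain.prior.to_dict(),
        "n_samples": len(chain),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for s in chain.samples:
            rec = {
                "iteration": s.iteration,
                "couples": list(s.config.couples),
                "singletons": list(s.config.singletons),
                "beta0": s.coeffs.beta0,
                "a": s.coeffs.a.tolist(),
                "b": s.coeffs.b.tolist(),
                "s_a": s.coeffs.s_a,
                "s_b": s.coeffs.s_b,
            }
            fh.write(json.dumps(rec) + "\n")


def load_chain(path) -> Chain:
    """Load a chain persisted by :func:`persist_chain` (exact round trip)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ChainFormatError(f"{path}: empty chain file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise ChainFormatError(f"{path}: malformed header: {e}") from e
    if header.get("format") != _CHAIN_FORMAT:
        raise ChainFormatError(f"{path}: not a {_CHAIN_FORMAT} file")
    if header.get("version") != _CHAIN_VERSION:
        raise ChainFormatError(
            f"{path}: unsupported chain version {header.get('version')}")
    expected = header.get("n_samples")
    samples = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            samples.append(ChainSample(
                iteration=rec["iteration"],
                config=ModelConfiguration(tuple(rec["couples"]),
                                          tuple(rec["singletons"])),
                coeffs=CoefficientState(rec["beta0"], np.array(rec["a"]),
                                        np.array(rec["b"]), rec["s_a"],
                                        rec["s_b"]),
            ))
        except (json.JSONDecodeError, KeyError) as e:
            raise ChainFormatError(f"{path}:{ln}: malformed sample record: {e}") from e
    if expected is not None and len(samples) != expected:
        raise ChainFormatError(
            f"{path}: truncated chain file: header promises {expected} samples, "
            f"found {len(samples)}")
    return Chain(samples=samples,
                 settings=ChainSettings.from_dict(header["settings"]),
                 prior=PriorSpec.from_dict(header["prior"]),
                 p=header["p"],
                 pair_ids=tuple(header["pair_ids"]))
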