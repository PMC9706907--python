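"""Data model for censored child-survival records and region adjacency.

Child-level records carry a time on study in months (age at death for
children who died, age at interview for children alive at the survey),
an event indicator (1 = death observed, 0 = right-censored), a region
identifier, and covariates. Regions live on an adjacency graph used by
the intrinsic CAR spatial prior.

Conventions
-----------
* Time is measured in MONTHS on the 0-59 eligibility window (horizon 60).
* Deaths reported at completed age 0 months are assigned 0.5 months (a
  half-interval convention) so that log-time likelihoods are defined.
* Records missing time, event, or region are dropped (complete-case) and
  counted in the drop log.
* Region labels are arbitrary strings mapped to contiguous 0-based
  indices; the mapping is persisted alongside outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_HORIZON = 60.0  # months; the 0-59 month eligibility window
ZERO_AGE_DEATH_TIME = 0.5  # half-interval convention for deaths at age 0 months

AGE_MIN, AGE_MAX = 15, 49  # maternal age support in years
N_AGE_BINS = AGE_MAX - AGE_MIN + 1  # 35 one-year bins, re-coded 1..35


class SchemaError(ValueError):
    """A required column is missing or malformed in an input table."""


# ---------------------------------------------------------------------------
# adjacency graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric region adjacency with the matrices the ICAR prior needs.

    Attributes
    ----------
    labels : tuple of str
        Node labels in index order; ``labels[i]`` is the region with index i.
    W : ndarray, shape (G, G)
        Binary symmetric adjacency, zero diagonal.
    """

    labels: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if W.shape[0] != len(self.labels):
            raise ValueError("labels and adjacency matrix disagree on node count")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-loops are not allowed in a region adjacency")
        if not np.array_equal(W, W.T):
            raise ValueError("adjacency matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def D(self) -> np.ndarray:
        """Diagonal degree matrix, D_ii = sum_j W_ij."""
        return np.diag(self.W.sum(axis=1).astype(float))

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1).astype(float)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Unordered node pairs (i < j) with W_ij = 1."""
        i, j = np.nonzero(np.triu(self.W))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def components(self) -> list[np.ndarray]:
        """Connected components as sorted index arrays."""
        g = nx.from_numpy_array(self.W)
        return [np.array(sorted(c)) for c in nx.connected_components(g)]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}") from None

    @classmethod
    def from_edges(
        cls, labels: Sequence[str], edges: Sequence[tuple[str, str]]
    ) -> "AdjacencyGraph":
        idx = {lab: i for i, lab in enumerate(labels)}
        W = np.zeros((len(labels), len(labels)), dtype=int)
        for a, b in edges:
            if a not in idx or b not in idx:
                raise KeyError(f"edge ({a!r}, {b!r}) references an unknown node")
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            W[idx[a], idx[b]] = W[idx[b], idx[a]] = 1
        return cls(labels=tuple(labels), W=W)

    @classmethod
    def lattice(cls, rows: int, cols: int) -> "AdjacencyGraph":
        """Rook-neighbourhood lattice (the default synthetic spatial layout)."""
        labels = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
        edges = []
        for i in range(rows):
            for j in range(cols):
                if j + 1 < cols:
                    edges.append((f"r{i}c{j}", f"r{i}c{j + 1}"))
                if i + 1 < rows:
                    edges.append((f"r{i}c{j}", f"r{i + 1}c{j}"))
        return cls.from_edges(labels, edges)

    def write(self, path: str | Path) -> None:
        """Write in the plain adjacency-list format ``node: nbr1 nbr2 ...``."""
        lines = []
        for i, lab in enumerate(self.labels):
            nbrs = " ".join(self.labels[j] for j in np.nonzero(self.W[i])[0])
            lines.append(f"{lab}: {nbrs}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path: str | Path) -> AdjacencyGraph:
    """Read an adjacency-list file, one ``node: neighbor ...`` line per node.

    Every node must have its own line (possibly with no neighbours).
    Asymmetric listings are symmetrized with a warning; self-loops and
    neighbour labels without a line of their own are errors.
    """
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    nbrs: dict[str, list[str]] = {}
    for ln in lines:
        if ":" not in ln:
            raise SchemaError(f"malformed adjacency line {ln!r}")
        node, _, rest = ln.partition(":")
        node = node.strip()
        if node in nbrs:
            raise SchemaError(f"duplicate adjacency line for node {node!r}")
        nbrs[node] = rest.split()
    labels = list(nbrs)
    idx = {lab: i for i, lab in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)), dtype=int)
    for node, ns in nbrs.items():
        for nb in ns:
            if nb == node:
                raise ValueError(f"self-loop on node {node!r}")
            if nb not in idx:
                raise KeyError(f"neighbor {nb!r} of {node!r} has no node line")
            W[idx[node], idx[nb]] = 1
    if not np.array_equal(W, W.T):
        warnings.warn("asymmetric adjacency list; symmetrizing", stacklevel=2)
        W = np.maximum(W, W.T)
    return AdjacencyGraph(labels=tuple(labels), W=W)


def adjacency_from_geojson(path: str | Path, label_property: str) -> AdjacencyGraph:
    """Derive rook adjacency from GeoJSON polygons (shared-boundary test).

    Polygons whose boundaries intersect in more than a point are neighbours.
    Requires ``shapely``; only used when polygon inputs are supplied.
    """
    from shapely.geometry import shape  # local import: optional dependency

    gj = json.loads(Path(path).read_text())
    feats = gj["features"]
    labels = [str(f["properties"][label_property]) for f in feats]
    geoms = [shape(f["geometry"]) for f in feats]
    W = np.zeros((len(labels), len(labels)), dtype=int)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if not inter.is_empty and inter.length > 0:
                W[i, j] = W[j, i] = 1
    return AdjacencyGraph(labels=tuple(labels), W=W)


# ---------------------------------------------------------------------------
# observations and datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CensoredObservation:
    """One child-level record: y = min(t, C) months and delta = 1{t <= C}."""

    time_on_study: float
    event: int
    region_id: str
    maternal_age: float | None = None
    birth_weight: float | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time_on_study > 0:
            raise ValueError("time_on_study must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.birth_weight is not None and not self.birth_weight > 0:
            raise ValueError("birth_weight must be positive when present")


@dataclass(frozen=True)
class Covariate:
    """One entry of a covariate specification.

    ``kind`` is "categorical" (dummy-coded, ``reference`` level omitted) or
    "continuous" (passed through unchanged).
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name!r} needs a reference level")


@dataclass
class SurvivalDataset:
    """Design-ready censored survival data.

    The nonlinear and spatial design matrices are stored as index vectors
    (each child maps to exactly one maternal-age bin and one region); dense
    incidence matrices are available as properties.
    """

    time: np.ndarray  # (n,) months, > 0
    event: np.ndarray  # (n,) in {0,1}
    region_idx: np.ndarray  # (n,) 0-based into graph labels
    graph: AdjacencyGraph
    X: np.ndarray  # (n, p) fixed-effect design
    x_names: list[str]
    age_bin: np.ndarray | None = None  # (n,) 0-based, 0..N_AGE_BINS-1
    maternal_age: np.ndarray | None = None  # (n,) years
    horizon: float = DEFAULT_HORIZON
    drop_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.region_idx = np.asarray(self.region_idx, dtype=int)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.n and self.X.size == 0:
            self.X = np.empty((self.n, 0))
        n = self.n
        for name, arr in (("event", self.event), ("region_idx", self.region_idx)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n {n}")
        if self.X.shape[0] != n:
            raise ValueError("fixed design row count mismatch")
        if self.X.shape[1] != len(self.x_names):
            raise ValueError("x_names does not match design columns")
        if np.any(self.time <= 0):
            raise ValueError("all times must be positive")
        if np.any(self.time > self.horizon):
            raise ValueError(f"times exceed the study horizon {self.horizon}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")
        if self.region_idx.min(initial=0) < 0 or (
            self.n and self.region_idx.max() >= self.graph.n_nodes
        ):
            raise ValueError("region index outside the adjacency graph")
        if self.age_bin is not None:
            self.age_bin = np.asarray(self.age_bin, dtype=int)
            if len(self.age_bin) != n:
                raise ValueError("age_bin length mismatch")
            if self.n and (self.age_bin.min() < 0 or self.age_bin.max() >= N_AGE_BINS):
                raise ValueError("age bin outside 1..35 after re-coding")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_regions(self) -> int:
        return self.graph.n_nodes

    @property
    def n_age_bins(self) -> int:
        return N_AGE_BINS if self.age_bin is not None else 0

    @property
    def spatial_design(self) -> np.ndarray:
        """Dense n x G incidence w: one 1 per row at the child's region."""
        w = np.zeros((self.n, self.n_regions))
        w[np.arange(self.n), self.region_idx] = 1.0
        return w

    @property
    def nonlinear_design(self) -> np.ndarray:
        """Dense n x r incidence z: one 1 per row at the maternal-age bin."""
        if self.age_bin is None:
            raise ValueError("dataset has no maternal-age binning")
        z = np.zeros((self.n, N_AGE_BINS))
        z[np.arange(self.n), self.age_bin] = 1.0
        return z

    @property
    def death_rate(self) -> float:
        return float(self.event.mean()) if self.n else float("nan")

    @property
    def censoring_rate(self) -> float:
        return 1.0 - self.death_rate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.time,
                "event": self.event,
                "region": [self.graph.labels[i] for i in self.region_idx],
            }
        )
        if self.maternal_age is not None:
            df["maternal_age"] = self.maternal_age
        for j, name in enumerate(self.x_names):
            df[f"x:{name}"] = self.X[:, j]
        return df

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the canonical CSV plus a JSON sidecar (schema and label map)."""
        csv_path = Path(csv_path)
        # %.17g round-trips every double exactly
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        sidecar = {
            "x_names": self.x_names,
            "region_labels": list(self.graph.labels),
            "horizon": self.horizon,
            "has_age_bin": self.age_bin is not None,
            "drop_log": self.drop_log,
        }
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".json")
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(
        cls, csv_path: str | Path, graph: AdjacencyGraph, sidecar_path: str | Path | None = None
    ) -> "SurvivalDataset":
        csv_path = Path(csv_path)
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".json")
        sidecar = json.loads(Path(sidecar_path).read_text())
        df = pd.read_csv(csv_path, float_precision="round_trip")
        x_names = sidecar["x_names"]
        X = df[[f"x:{n}" for n in x_names]].to_numpy(dtype=float) if x_names else np.empty((len(df), 0))
        age = df["maternal_age"].to_numpy(dtype=float) if "maternal_age" in df else None
        age_bin = _bin_maternal_age(age) if sidecar.get("has_age_bin") and age is not None else None
        return cls(
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
            region_idx=np.array([graph.index_of(str(r)) for r in df["region"]]),
            graph=graph,
            X=X,
            x_names=list(x_names),
            age_bin=age_bin,
            maternal_age=age,
            horizon=float(sidecar.get("horizon", DEFAULT_HORIZON)),
        )


def _bin_maternal_age(age: np.ndarray) -> np.ndarray:
    """Integer-year maternal-age bins: 15 -> 0, ..., 49 -> 34 (re-code 1..35)."""
    bins = np.floor(np.asarray(age, dtype=float)).astype(int) - AGE_MIN
    if bins.size and (bins.min() < 0 or bins.max() >= N_AGE_BINS):
        raise ValueError(f"maternal age outside {AGE_MIN}..{AGE_MAX}")
    return bins


# ---------------------------------------------------------------------------
# readers / design construction
# ---------------------------------------------------------------------------


def read_survival_table(
    path: str | Path,
    schema: Mapping[str, str],
    graph: AdjacencyGraph,
    covariate_spec: Sequence[Covariate] = (),
    horizon: float = DEFAULT_HORIZON,
) -> SurvivalDataset:
    """Read a delimited child-records table into a design-ready dataset.

    ``schema`` maps the roles ``age_at_death`` (months, empty if alive),
    ``age_at_interview`` (months), ``region``, and optionally
    ``maternal_age`` to column names of the file. Time on study is the age
    at death for children who died, else the age at interview (censored).
    Deaths at completed age 0 months get time 0.5 months. Records with
    missing time, event, or region are dropped and counted.
    """
    for role in ("age_at_death", "age_at_interview", "region"):
        if role not in schema:
            raise SchemaError(f"schema is missing the {role!r} role")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"input file lacks columns {missing}")

    death = pd.to_numeric(df[schema["age_at_death"]], errors="coerce")
    interview = pd.to_numeric(df[schema["age_at_interview"]], errors="coerce")
    region = df[schema["region"]].astype("string")

    event = death.notna().astype(int).to_numpy()
    time = np.where(event == 1, death.to_numpy(dtype=float), interview.to_numpy(dtype=float))
    time = np.where((event == 1) & (time == 0.0), ZERO_AGE_DEATH_TIME, time)

    reasons = {
        "missing_time": ~np.isfinite(time),
        "missing_region": region.isna().to_numpy(),
    }
    with np.errstate(invalid="ignore"):
        reasons["nonpositive_time"] = np.isfinite(time) & (time <= 0)
        reasons["beyond_horizon"] = np.isfinite(time) & (time > horizon)
    bad = np.zeros(len(df), dtype=bool)
    drop_log = {}
    for why, mask in reasons.items():
        new = mask & ~bad
        if new.any():
            drop_log[why] = int(new.sum())
        bad |= mask
    keep = ~bad
    drop_log["kept"] = int(keep.sum())
    drop_log["dropped"] = int(bad.sum())

    region_idx = np.array([graph.index_of(str(r)) for r in region[keep]])
    raw = df.loc[keep].reset_index(drop=True)
    age = (
        pd.to_numeric(raw[schema["maternal_age"]], errors="coerce").to_numpy(dtype=float)
        if "maternal_age" in schema
        else None
    )

    X, x_names = _encode_covariates(raw, covariate_spec)
    return SurvivalDataset(
        time=time[keep],
        event=event[keep],
        region_idx=region_idx,
        graph=graph,
        X=X,
        x_names=x_names,
        age_bin=_bin_maternal_age(age) if age is not None else None,
        maternal_age=age,
        horizon=horizon,
        drop_log=drop_log,
    )


def _encode_covariates(
    df: pd.DataFrame, spec: Sequence[Covariate]
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in spec:
        if cov.name not in df.columns:
            raise SchemaError(f"covariate column {cov.name!r} not in data")
        if cov.kind == "continuous":
            cols.append(pd.to_numeric(df[cov.name], errors="raise").to_numpy(dtype=float))
            names.append(cov.name)
            continue
        values = df[cov.name].astype(str)
        levels = sorted(set(values))
        if cov.reference not in levels:
            warnings.warn(
                f"reference level {cov.reference!r} of {cov.name!r} absent from data",
                stacklevel=3,
            )
        for lev in levels:
            if lev == cov.reference:
                continue
            cols.append((values == lev).to_numpy(dtype=float))
            names.append(f"{cov.name}={lev}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def build_designs(
    records: pd.DataFrame,
    covariate_spec: Sequence[Covariate],
    graph: AdjacencyGraph,
    horizon: float = DEFAULT_HORIZON,
) -> SurvivalDataset:
    """Build a design-ready dataset from canonical records.

    ``records`` must have columns ``time``, ``event``, ``region`` and any
    covariate columns named in ``covariate_spec``; an optional
    ``maternal_age`` column (years, 15..49) is binned to the 35 one-year
    bins of the nonlinear term. Categorical covariates are dummy-coded
    with the stated reference level omitted.
    """
    for col in ("time", "event", "region"):
        if col not in records.columns:
            raise SchemaError(f"records are missing column {col!r}")
    X, x_names = _encode_covariates(records, covariate_spec)
    age = (
        records["maternal_age"].to_numpy(dtype=float)
        if "maternal_age" in records.columns
        else None
    )
    return SurvivalDataset(
        time=records["time"].to_numpy(dtype=float),
        event=records["event"].to_numpy(dtype=int),
        region_idx=np.array([graph.index_of(str(r)) for r in records["region"]]),
        graph=graph,
        X=X,
        x_names=x_names,
        age_bin=_bin_maternal_age(age) if age is not None else None,
        maternal_age=age,
        horizon=horizon,
    )
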