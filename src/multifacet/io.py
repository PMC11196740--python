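"""File formats and run configuration.

The canonical on-disk format is a layered edge list: a delimited text file
with header ``source,target,layer,weight`` (``weight`` optional, default 1).
It is the natural shape for sparse directed multiplex data.  A converter is
provided for one square weight-matrix text file per layer.

All writers emit plain comma-separated text with fixed headers and 6-decimal
fixed formatting for reals; an undefined overlap probability is written as
``NA``.  Identical configuration and input produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import MultifacetError
from .evaluate import ModuleSummary, ScanRow
from .multiplex import Layer, MultiplexNetwork, Partition

logger = logging.getLogger("multifacet")

PathLike = Union[str, Path]

_MODES = ("ng", "exclusion", "inclusion", "multi")


def read_multiplex(path: PathLike) -> MultiplexNetwork:
    """Read a layered edge list into a multiplex network.

    Node identifiers are arbitrary strings; the shared node order is the
    sorted union of identifiers appearing in any layer.  Duplicate
    ``(source, target, layer)`` rows are summed with a logged warning.
    Missing columns, negative weights and self-loops are rejected with the
    offending row number.
    """
    df = pd.read_csv(path, dtype={"source": str, "target": str, "layer": str})
    missing = {"source", "target", "layer"} - set(df.columns)
    if missing:
        raise MultifacetError(f"missing required column(s) {sorted(missing)} in {path}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    for row, (src, dst, w) in enumerate(zip(df["source"], df["target"], df["weight"]), start=2):
        if w < 0:
            raise MultifacetError(f"negative weight {w} at row {row} of {path}")
        if src == dst:
            raise MultifacetError(f"self-loop {src!r} -> {src!r} at row {row} of {path}")
    dup = df.duplicated(subset=["source", "target", "layer"])
    if dup.any():
        logger.warning(
            "%d duplicate (source, target, layer) rows in %s; weights summed", int(dup.sum()), path
        )
    edges = [
        (src, dst, layer, float(w))
        for src, dst, layer, w in zip(df["source"], df["target"], df["layer"], df["weight"])
    ]
    return MultiplexNetwork.from_edges(edges, directed=True)


def write_multiplex(M: MultiplexNetwork, path: PathLike) -> None:
    """Write a multiplex as a layered edge list (canonical sorted order)."""
    records = []
    for name in M.layer_names:
        w = M.layers[name].weights
        for i, src in enumerate(M.nodes):
            for j, dst in enumerate(M.nodes):
                if w[i, j] != 0:
                    records.append((src, dst, name, w[i, j]))
    df = pd.DataFrame(records, columns=["source", "target", "layer", "weight"])
    df = df.sort_values(["layer", "source", "target"], kind="stable")
    df.to_csv(path, index=False, float_format="%.6f")


def read_matrix_layers(paths: dict[str, PathLike]) -> MultiplexNetwork:
    """Converter: build a multiplex from one square matrix text file per layer.

    Each file holds a whitespace/comma-delimited square matrix with a header
    row and index column of node identifiers; all files must agree on them.
    """
    layers = []
    nodes: Optional[tuple[str, ...]] = None
    for name, path in paths.items():
        df = pd.read_csv(path, index_col=0)
        order = tuple(str(c) for c in df.index)
        if tuple(str(c) for c in df.columns) != order:
            raise MultifacetError(f"matrix file {path} rows and columns disagree")
        if nodes is None:
            nodes = order
        elif order != nodes:
            raise MultifacetError(f"matrix file {path} node order differs between layers")
        layers.append(Layer(name=name, node_order=nodes, weights=df.to_numpy(dtype=float)))
    if not layers:
        raise MultifacetError("no matrix files given")
    return MultiplexNetwork.from_layers(layers)


def write_partition(part: Partition, path: PathLike) -> None:
    rows = [(str(v), part.assignment[v]) for v in sorted(part.assignment, key=str)]
    pd.DataFrame(rows, columns=["node", "community"]).to_csv(path, index=False)


def read_partition(path: PathLike) -> Partition:
    df = pd.read_csv(path, dtype={"node": str})
    if not {"node", "community"} <= set(df.columns):
        raise MultifacetError(f"partition file {path} needs columns node,community")
    return Partition(assignment=dict(zip(df["node"], df["community"].astype(int))))


def _fmt(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.6f}"


def write_summary(rows: Sequence[ModuleSummary], path: PathLike) -> None:
    lines = ["community,n_members,Q_c,overlap_prob"]
    for r in rows:
        lines.append(f"{r.community_id},{r.n_members},{r.Q_c:.6f},{_fmt(r.overlap_prob)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_scan(rows: Sequence[ScanRow], path: PathLike) -> None:
    lines = ["promoted_layers,Q,nmi"]
    for r in rows:
        lines.append(f"{'+'.join(r.promoted_layers)},{_fmt(r.Q)},{_fmt(r.nmi_vs_baseline)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scan(path: PathLike) -> list[ScanRow]:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    rows = []
    for _, rec in df.iterrows():
        q = None if pd.isna(rec["Q"]) else float(rec["Q"])
        v = None if pd.isna(rec["nmi"]) else float(rec["nmi"])
        rows.append(ScanRow(tuple(str(rec["promoted_layers"]).split("+")), q, v))
    return rows


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one detection run."""

    input: str
    mode: str
    observed_layers: tuple[str, ...]
    null_layers: tuple[str, ...] = ()
    gamma: float = 1.0
    degree_mode: str = "as_printed"
    seed: int = 0
    restarts: int = 20
    output_prefix: str = "multifacet_run"

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_layers", tuple(self.observed_layers))
        object.__setattr__(self, "null_layers", tuple(self.null_layers))
        self.validate()

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise MultifacetError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if not self.observed_layers:
            raise MultifacetError("at least one observed layer is required")
        if self.mode == "ng" and self.null_layers:
            raise MultifacetError("ng mode takes no null layers")
        if self.mode in ("exclusion", "inclusion"):
            if len(self.observed_layers) != 1 or len(self.null_layers) != 1:
                raise MultifacetError(
                    f"{self.mode} mode needs exactly one observed and one null layer"
                )
            if self.observed_layers[0] == self.null_layers[0]:
                raise MultifacetError("observed and null layers must differ")
        if self.mode == "multi":
            if not self.null_layers:
                raise MultifacetError("multi mode needs at least one null layer")
            if not set(self.null_layers) <= set(self.observed_layers):
                raise MultifacetError("multi mode requires null layers to be observed layers")
        if self.gamma < 0:
            raise MultifacetError("gamma must be non-negative")
        if self.restarts < 1:
            raise MultifacetError("restarts must be >= 1")
        if self.degree_mode not in ("as_printed", "directed"):
            raise MultifacetError(f"unknown degree_mode {self.degree_mode!r}")


def read_config(path: PathLike) -> dict[str, str]:
    """Parse a flat ``key: value`` configuration file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise MultifacetError(f"malformed config line {lineno}: {raw!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out
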