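"""Readers, writers and run configuration.

File conventions:

* count tables — TSV, ASVs as rows, samples as columns, header row of sample
  ids (the in-memory :class:`CountTable` is samples x ASVs; the reader
  transposes);
* sample metadata — TSV with columns ``sample``, ``location``, ``reactor``;
* current traces — CSV with columns ``time_s``, ``current_A``; electrode
  area and liquid volume live in the run configuration;
* substrate deltas — TSV with columns ``substrate``, ``delta_mol_per_L``;
* trees — Newick; networks — edge-list TSV and GraphML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .electrochem import CurrentTrace, SubstrateDelta


def read_count_table(path, meta_path=None) -> CountTable:
    """Read an ASV-by-sample TSV into a :class:`CountTable`.

    Validates integer counts and unique ids; errors cite the offending line
    number (1-based, header = line 1).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    lines = text.splitlines()
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids in header")
    asv_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        asv_ids.append(fields[0])
        row = []
        for val in fields[1:]:
            try:
                count = int(val)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer count {val!r}"
                ) from None
            if count < 0:
                raise ValueError(f"{path}: line {lineno}: negative count {count}")
            row.append(count)
        rows.append(row)
    if len(set(asv_ids)) != len(asv_ids):
        dups = sorted({a for a in asv_ids if asv_ids.count(a) > 1})
        raise ValueError(f"{path}: duplicate ASV ids: {dups}")
    counts = pd.DataFrame(rows, index=asv_ids, columns=sample_ids).T
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return CountTable(counts, meta)


def write_count_table(table: CountTable, path, meta_path=None) -> None:
    """Write a count table (ASVs as rows) and optionally its metadata."""
    table.counts.T.to_csv(path, sep="\t", index_label="ASV")
    if meta_path is not None and table.sample_meta is not None:
        table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_trace(path, electrode_area: float, volume: float) -> CurrentTrace:
    """Read a time_s/current_A CSV into a :class:`CurrentTrace`."""
    df = pd.read_csv(path)
    for col in ("time_s", "current_A"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return CurrentTrace(
        df["time_s"].to_numpy(float), df["current_A"].to_numpy(float),
        electrode_area, volume,
    )


def write_trace(trace: CurrentTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "current_A": trace.current}).to_csv(
        path, index=False
    )


def read_substrate_deltas(path) -> list[SubstrateDelta]:
    """Read a substrate/delta_mol_per_L TSV (consumed amounts, positive)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("substrate", "delta_mol_per_L"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        SubstrateDelta(row.substrate, float(row.delta_mol_per_L))
        for row in df.itertuples()
    ]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edge-list TSV: node_i, node_j, sign, sparcc_r, spearman_rho, p-values."""
    rows = [
        {
            "node_i": i,
            "node_j": j,
            "sign": "+" if d.get("sign", 1) > 0 else "-",
            "sparcc_r": d.get("sparcc_r", np.nan),
            "spearman_rho": d.get("spearman_rho", np.nan),
            "p_sparcc": d.get("p_sparcc", np.nan),
            "p_spearman": d.get("p_spearman", np.nan),
        }
        for i, j, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows,
        columns=["node_i", "node_j", "sign", "sparcc_r", "spearman_rho",
                 "p_sparcc", "p_spearman"],
    ).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


@dataclasses.dataclass
class RunConfig:
    """All stage parameters with the study defaults.

    Defaults: 10-sample (5-min) current bins, 1 A/m2 lag threshold, 70-ml
    volume; ASV filter at >= 2 samples and > 0.1% relative abundance;
    correlation threshold 0.6 at alpha 0.05; 999 Raup-Crick iterations.
    """

    out_dir: str = "mecnet_out"
    seed: int = 0
    # electrochem
    electrode_area: float = 1e-3
    volume: float = 0.07
    group_size: int = 10
    lag_threshold: float = 1.0
    electrons_per_mol: dict = dataclasses.field(
        default_factory=lambda: {"acetate": 8, "propionate": 14, "butyrate": 20}
    )
    # diversity
    diversity_order: float = 1.0
    raup_crick_iterations: int = 999
    mantel_permutations: int = 999
    # network
    min_samples: int = 2
    min_relabund: float = 0.001
    merge_epsilon: float = 0.004
    correlation_threshold: float = 0.6
    alpha: float = 0.05
    sparcc_resamples: int = 20
    sparcc_bootstraps: int = 99

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
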