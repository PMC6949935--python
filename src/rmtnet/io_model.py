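"""Domain types and tabular/graph I/O for the network pipeline.

The pipeline moves an OTU abundance table (taxa x samples) and a sample
metadata table (samples x environmental variables) through similarity-matrix
construction, network building and environment linkage.  Everything here is
plain tab-delimited text (comma auto-detected) so that exports can be fed
straight into spreadsheet tools or Cytoscape.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("rmtnet")
if not logger.handlers:  # library default: quiet unless the app configures it
    logger.addHandler(logging.NullHandler())

#: significant digits used when floats are written to disk
FLOAT_FORMAT = "%.6g"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """An OTU x sample abundance matrix with optional taxonomy and grouping.

    Parameters
    ----------
    otu_ids : list of str
        Unique OTU identifiers (row labels).
    sample_ids : list of str
        Unique sample identifiers (column labels).
    abundance : ndarray of shape (n_otus, n_samples)
        Non-negative, finite abundances (counts or relative abundances).
    taxonomy : dict, optional
        Maps otu_id -> lineage string (``k__...;p__...;...``).
    group : dict, optional
        Maps sample_id -> group label (e.g. crack vs control soils).
    is_log_scale : bool
        True for log-transformed tables, whose cells may be negative;
        raw abundance tables must be non-negative.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    abundance: np.ndarray
    taxonomy: dict[str, str] | None = None
    group: dict[str, str] | None = None
    is_log_scale: bool = False

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        for name, ids in (("OTU", self.otu_ids), ("sample", self.sample_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValidationError(f"duplicate {name} IDs: {sorted(dups)}")
        if len(self.sample_ids) < 2:
            raise ValidationError("an OTU table needs at least 2 samples")
        if not np.all(np.isfinite(self.abundance)):
            bad = np.argwhere(~np.isfinite(self.abundance))[0]
            raise ValidationError(
                f"non-finite abundance at OTU {self.otu_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if not self.is_log_scale and np.any(self.abundance < 0):
            bad = np.argwhere(self.abundance < 0)[0]
            raise ValidationError(
                f"negative abundance at OTU {self.otu_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.otu_ids,
                            columns=self.sample_ids)

    def phylum_of(self, otu_id: str) -> str:
        """Phylum label parsed from the lineage string (``p__`` prefix)."""
        if self.taxonomy is None:
            return "Unclassified"
        return parse_phylum(self.taxonomy.get(otu_id, ""))

    def subset_otus(self, keep: Sequence[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in keep]
        tax = ({o: self.taxonomy[o] for o in keep if o in self.taxonomy}
               if self.taxonomy else None)
        return OtuTable(list(keep), list(self.sample_ids),
                        self.abundance[idx, :], tax, self.group,
                        self.is_log_scale)

    def subset_samples(self, keep: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        grp = ({s: self.group[s] for s in keep if s in self.group}
               if self.group else None)
        return OtuTable(list(self.otu_ids), list(keep),
                        self.abundance[:, idx], self.taxonomy, grp,
                        self.is_log_scale)

    def with_abundance(self, values: np.ndarray,
                       is_log_scale: bool | None = None) -> "OtuTable":
        return replace(self, abundance=np.asarray(values, dtype=float),
                       is_log_scale=(self.is_log_scale if is_log_scale is None
                                     else is_log_scale))


@dataclass
class SampleMetadata:
    """Per-sample environmental variables (soil water, temperature, pH, ...).

    Missing values are carried as NaN, never silently replaced by zero;
    downstream correlations drop them pairwise.
    """

    sample_ids: list[str]
    variables: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)
    group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        dups = _duplicates(self.sample_ids)
        if dups:
            raise ValidationError(f"duplicate sample IDs: {sorted(dups)}")
        n = len(self.sample_ids)
        for name, vec in self.variables.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ValidationError(
                    f"variable {name!r} has length {vec.shape}, expected {n}")
            self.variables[name] = vec

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variable_names(self) -> list[str]:
        return list(self.variables)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.variables, index=self.sample_ids)

    def subset_samples(self, keep: Sequence[str]) -> "SampleMetadata":
        idx = [self.sample_ids.index(s) for s in keep]
        variables = {k: v[idx] for k, v in self.variables.items()}
        grp = ({s: self.group[s] for s in keep if s in self.group}
               if self.group else None)
        return SampleMetadata(list(keep), variables, dict(self.units), grp)


@dataclass
class SimilarityMatrix:
    """Absolute Pearson correlation between retained OTUs.

    ``values`` holds |r| in [0, 1]; ``raw_sign`` records sign(r) so that
    positive/negative co-occurrence survives the absolute value.  The
    diagonal is stored as 1 but is never a candidate link.
    """

    otu_ids: list[str]
    values: np.ndarray
    raw_sign: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.raw_sign = np.asarray(self.raw_sign)
        n = len(self.otu_ids)
        if self.values.shape != (n, n) or self.raw_sign.shape != (n, n):
            raise ValidationError("similarity matrices must be square over otu_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("similarity values must lie in [0, 1]")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


@dataclass
class EcoNetwork:
    """Undirected co-occurrence network over thresholded similarities.

    Edges are (i, j, weight, sign) with i < j by node index; weight is the
    similarity |r| and sign the sign of the underlying correlation.  Nodes
    without any qualifying link are dropped before construction.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, int]]
    threshold: float
    partition: dict[str, int] | None = None
    node_taxa: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen = set()
        degree = {n: 0 for n in self.nodes}
        for a, b, w, s in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on {a!r}")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)
            if w < self.threshold - 1e-12:
                raise ValidationError(
                    f"edge {key} weight {w} below threshold {self.threshold}")
            degree[a] += 1
            degree[b] += 1
        isolated = [n for n, d in degree.items() if d == 0]
        if isolated:
            raise ValidationError(f"isolated nodes in network: {isolated}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, w, s in self.edges:
            g.add_edge(a, b, weight=float(w), sign=int(s))
        if self.partition:
            nx.set_node_attributes(g, self.partition, "module")
        if self.node_taxa:
            nx.set_node_attributes(g, self.node_taxa, "phylum")
        return g


@dataclass
class TopologyPanel:
    """The per-network topology summary (one column of the comparison table)."""

    n_original_otus: int
    total_nodes: int
    total_links: int
    r_square_power_law: float
    avg_degree: float
    avg_clustering: float
    avg_path_distance: float
    geodesic_efficiency: float
    maximal_degree: int
    density: float
    transitivity: float
    connectedness: float
    n_modules: int
    n_modules_large: int
    modularity: float
    threshold: float

    def to_series(self, name: str = "network") -> pd.Series:
        rows = {
            "Number of original OTUs": self.n_original_otus,
            "Similarity threshold": self.threshold,
            "Total nodes": self.total_nodes,
            "Total links": self.total_links,
            "R square of power-law": round(self.r_square_power_law, 3),
            "Average degree": round(self.avg_degree, 3),
            "Average clustering coefficient": round(self.avg_clustering, 3),
            "Average path distance": round(self.avg_path_distance, 3),
            "Geodesic efficiency": round(self.geodesic_efficiency, 3),
            "Maximal degree": self.maximal_degree,
            "Density": round(self.density, 3),
            "Transitivity": round(self.transitivity, 3),
            "Connectedness": round(self.connectedness, 3),
            "Module": self.n_modules,
            "Module (>5 nodes)": self.n_modules_large,
            "Modularity": round(self.modularity, 3),
        }
        return pd.Series(rows, name=name)


@dataclass
class Config:
    """Run configuration; every numeric knob of the pipeline in one place.

    ``prevalence_rule`` is either an absolute sample count (int), a fraction
    of samples (float in (0, 1)), or the string ``"majority"`` for
    floor(n/2)+1 — the published parameterisation for 15-sample groups is
    8/15, i.e. the majority rule.
    """

    prevalence_rule: int | float | str = "majority"
    fill_value: float = 0.01
    pairwise_valid: bool = True
    threshold_mode: str = "fixed"          # "fixed" | "rmt_scan"
    fixed_threshold: float = 0.81
    scan_from: float = 0.99
    scan_to: float = 0.30
    scan_step: float = 0.01
    rmt_alpha: float = 0.05
    unfold_degree: int = 5
    min_module_size_for_reporting: int = 5
    permutations: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fill_value <= 0:
            raise ValidationError("fill_value must be positive (log10 follows)")
        if self.threshold_mode not in ("fixed", "rmt_scan"):
            raise ValidationError("threshold_mode must be 'fixed' or 'rmt_scan'")
        if not 0 < self.fixed_threshold < 1:
            raise ValidationError("fixed_threshold must lie in (0, 1)")
        if self.scan_from <= self.scan_to:
            raise ValidationError("scan_from must exceed scan_to")
        if self.scan_step <= 0:
            raise ValidationError("scan_step must be positive")
        if not 0 < self.rmt_alpha < 1:
            raise ValidationError("rmt_alpha must lie in (0, 1)")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read a flat ``key = value`` (TOML-compatible) config file."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for i in ids:
        if i in seen:
            dups.add(i)
        seen.add(i)
    return dups


_PHYLUM_RE = re.compile(r"p__([^;|]+)")


def parse_phylum(lineage: str) -> str:
    """Extract the phylum from a greengenes-style lineage string.

    Unparseable or empty lineages map to ``"Unclassified"`` so that node
    colouring by phylum is always total.
    """
    if not lineage:
        return "Unclassified"
    m = _PHYLUM_RE.search(lineage)
    if m:
        name = m.group(1).strip()
        return name if name else "Unclassified"
    return "Unclassified"


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def _check_header_unique(path: Path, sep: str, what: str) -> None:
    # pandas silently mangles duplicate column names; check the raw header
    header = path.open("r", encoding="utf-8").readline().rstrip("\n")
    cols = header.split(sep)[1:]
    dups = _duplicates(cols)
    if dups:
        raise ValidationError(
            f"duplicate {what} IDs in header of {path.name}: {sorted(dups)}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU table: first column OTU IDs, header row sample IDs.

    An optional final ``taxonomy`` column (case-insensitive) holds lineage
    strings.  Tabs are the canonical separator; a comma-separated file is
    auto-detected from the header line.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    _check_header_unique(path, sep, "sample")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    df.index = df.index.astype(str)

    dups = _duplicates(df.index)
    if dups:
        raise ValidationError(f"duplicate OTU IDs in {path.name}: {sorted(dups)}")

    taxonomy = None
    tax_cols = [c for c in df.columns if c.lower() == "taxonomy"]
    if tax_cols:
        taxonomy = {o: t for o, t in df[tax_cols[0]].items() if t}
        df = df.drop(columns=tax_cols)

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                v = float(cell)
            except ValueError:
                raise ValidationError(
                    f"non-numeric abundance {cell!r} at OTU {df.index[i]!r}, "
                    f"sample {col!r}") from None
            if v < 0:
                raise ValidationError(
                    f"negative abundance {v} at OTU {df.index[i]!r}, "
                    f"sample {col!r}")
            values[i, j] = v
    return OtuTable(list(df.index), [str(c) for c in df.columns], values,
                    taxonomy=taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_frame()
    if table.taxonomy:
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="OTU_ID")


def read_metadata(path: str | Path,
                  otu_table: OtuTable | None = None) -> SampleMetadata:
    """Read sample metadata: first column sample IDs, then variables.

    Non-numeric columns are treated as group labels (the first one becomes
    ``group``).  Blank cells become NaN, never zero.  If ``otu_table`` is
    given, the sample sets must match exactly.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    dups = _duplicates(df.index)
    if dups:
        raise ValidationError(f"duplicate sample IDs in {path.name}: {sorted(dups)}")

    group = None
    variables: dict[str, np.ndarray] = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        # a column that fails numeric coercion on every non-blank cell is a label
        non_blank = df[col].notna()
        if non_blank.any() and numeric[non_blank].isna().all():
            if group is None:
                group = {s: str(v) for s, v in df[col].items() if pd.notna(v)}
            continue
        variables[str(col)] = numeric.to_numpy(dtype=float)

    meta = SampleMetadata(list(df.index), variables, group=group)
    if otu_table is not None:
        a, b = set(otu_table.sample_ids), set(meta.sample_ids)
        if a != b:
            raise ValidationError(
                "sample mismatch between OTU table and metadata; "
                f"only in OTU table: {sorted(a - b)}; only in metadata: {sorted(b - a)}")
    return meta


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.to_frame()
    if meta.group:
        df.insert(0, "group", [meta.group.get(s, "") for s in meta.sample_ids])
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample")


def write_network(net: EcoNetwork, path: str | Path,
                  format: str = "edgelist") -> None:
    """Export a network as a TSV edge list or GraphML (Cytoscape-readable).

    The edge list carries source, target, weight, sign and a same_module
    flag; GraphML additionally stores module id and phylum per node.
    """
    path = Path(path)
    if format == "edgelist":
        part = net.partition or {}
        rows = []
        for a, b, w, s in net.edges:
            same = (part.get(a) == part.get(b)) if part else ""
            rows.append((a, b, w, s, same))
        df = pd.DataFrame(rows, columns=["source", "target", "weight",
                                         "sign", "same_module"])
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    elif format == "graphml":
        g = net.to_networkx()
        g.graph["threshold"] = float(net.threshold)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, threshold: float,
                 format: str = "edgelist") -> EcoNetwork:
    """Inverse of :func:`write_network`; round-trips the edge set exactly."""
    path = Path(path)
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t")
        edges = [(str(r.source), str(r.target), float(r.weight), int(r.sign))
                 for r in df.itertuples()]
        nodes = sorted({n for a, b, *_ in edges for n in (a, b)})
        return EcoNetwork(nodes, edges, threshold)
    elif format == "graphml":
        g = nx.read_graphml(path)
        edges = [(str(a), str(b), float(d["weight"]), int(d["sign"]))
                 for a, b, d in g.edges(data=True)]
        partition = {str(n): int(d["module"]) for n, d in g.nodes(data=True)
                     if "module" in d} or None
        taxa = {str(n): str(d["phylum"]) for n, d in g.nodes(data=True)
                if "phylum" in d} or None
        return EcoNetwork([str(n) for n in g.nodes], edges,
                          float(g.graph.get("threshold", threshold)),
                          partition=partition, node_taxa=taxa)
    raise ValueError(f"unknown network format {format!r}")
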