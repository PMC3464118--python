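"""Data model and file formats for 2-D landmark shape-genetics datasets.

The unit of observation is a :class:`LandmarkConfiguration` — one digitization
of one hemimandible (or any paired 2-D structure): ``k`` landmarks, a specimen
id, a strain id, a side (``L``/``R``) and a replicate number.  A
:class:`Dataset` bundles configurations with a strain covariate table
(:class:`StrainRecord`, mirroring the study design table: number of mice,
donor-genome megabases, segment and gene counts per congenic strain).

Supported formats
-----------------
* TPS (the ``LM=`` / ``ID=`` / ``SCALE=`` dialect written by TpsDig-style
  digitizers).  Specimen metadata is encoded in the ID string as
  ``<specimen>_<strain>_<L|R>_<replicate>`` or supplied via a sidecar table.
* Long-format landmark CSV (one row per landmark per configuration).
* Strain covariate CSV with header ``strain,n_mice,seg_mb,n_segments,n_genes``.
* Whitespace-separated adjacency edge lists over 1-based landmark indices.

Landmark indices are 1-based in every file and report; arrays are 0-based
internally.  Coordinates are unitless (centroid-size scaling removes units).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "StrainRecord",
    "Dataset",
    "AdjacencyGraph",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_strain_table",
    "write_strain_table",
    "read_adjacency",
    "load_strain_table",
    "load_template_shape",
    "load_adjacency",
    "DatasetError",
    "ParseError",
]

SIDES = ("L", "R")


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class DatasetError(ValueError):
    """Configurations are mutually inconsistent (e.g. mixed landmark counts)."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One digitization of one side of one specimen.

    ``coords`` is a ``(k, 2)`` float array; landmark order is fixed and must be
    identical across all configurations in a dataset.
    """

    specimen_id: str
    strain_id: str
    side: str
    replicate: int
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (k, 2), got {coords.shape}")
        if coords.shape[0] < 3:
            raise ValueError("need at least 3 landmarks")
        if not np.all(np.isfinite(coords)):
            raise ValueError(
                f"non-finite coordinates in {self.specimen_id} {self.side} r{self.replicate}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class StrainRecord:
    """One row of the strain covariate table.

    The reference (background) strain carries no donor segments; its ``seg_mb``
    and ``n_segments`` are zero and ``is_reference`` is set.
    """

    strain_id: str
    n_mice: int
    seg_mb: float = 0.0
    n_segments: int = 0
    n_genes: int = 0
    is_reference: bool = False

    def __post_init__(self):
        if self.n_mice < 1:
            raise ValueError(f"{self.strain_id}: n_mice must be >= 1")
        if self.seg_mb < 0 or self.n_segments < 0 or self.n_genes < 0:
            raise ValueError(f"{self.strain_id}: negative covariate")
        if self.is_reference and (self.seg_mb > 0 or self.n_segments > 0):
            raise ValueError(
                f"{self.strain_id}: reference strain must carry no donor segments"
            )


@dataclass
class AdjacencyGraph:
    """Undirected anatomical adjacency over landmarks ``1..k`` (1-based)."""

    k: int
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        g = nx.Graph()
        g.add_nodes_from(range(1, self.k + 1))
        for a, b in self.edges:
            if not (1 <= a <= self.k and 1 <= b <= self.k):
                raise ValueError(f"edge ({a}, {b}) outside 1..{self.k}")
            if a == b:
                raise ValueError(f"self-loop at landmark {a}")
            g.add_edge(a, b)
        if self.k and not nx.is_connected(g):
            comps = sorted(sorted(c) for c in nx.connected_components(g))
            raise ValueError(f"adjacency graph is disconnected; components: {comps}")
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def is_connected_block(self, landmarks: Iterable[int]) -> bool:
        """True when the induced subgraph on ``landmarks`` (1-based) is connected."""
        sub = self._graph.subgraph(list(landmarks))
        return sub.number_of_nodes() > 0 and nx.is_connected(sub)


@dataclass
class Dataset:
    """Landmark configurations plus the strain covariate table."""

    configurations: list[LandmarkConfiguration]
    strain_table: list[StrainRecord] = field(default_factory=list)

    @property
    def landmark_count(self) -> int:
        if not self.configurations:
            raise DatasetError("empty dataset")
        return self.configurations[0].k

    def validate(self) -> list[str]:
        """Check invariants; returns human-readable warnings for incomplete
        specimens (missing sides/replicates), raises for hard violations."""
        if not self.configurations:
            raise DatasetError("empty dataset")
        k = self.configurations[0].k
        for c in self.configurations:
            if c.k != k:
                raise DatasetError(
                    f"mixed landmark counts: {c.specimen_id} has k={c.k}, expected {k}"
                )
        known = {r.strain_id for r in self.strain_table}
        if known:
            for c in self.configurations:
                if c.strain_id not in known:
                    raise DatasetError(
                        f"strain {c.strain_id!r} of specimen {c.specimen_id!r} "
                        "missing from strain table"
                    )
        warnings: list[str] = []
        meta = self.meta()
        reps_per = meta.groupby(["specimen", "side"]).size()
        r_max = int(reps_per.max())
        for spec, grp in meta.groupby("specimen"):
            sides = set(grp["side"])
            if sides != set(SIDES):
                warnings.append(f"specimen {spec}: missing side(s) {set(SIDES) - sides}")
            for side in sides:
                n = len(grp[grp["side"] == side])
                if n != r_max:
                    warnings.append(
                        f"specimen {spec} side {side}: {n} replicate(s), expected {r_max}"
                    )
        return warnings

    def meta(self) -> pd.DataFrame:
        """Metadata table, one row per configuration (same order)."""
        return pd.DataFrame(
            {
                "specimen": [c.specimen_id for c in self.configurations],
                "strain": [c.strain_id for c in self.configurations],
                "side": [c.side for c in self.configurations],
                "replicate": [c.replicate for c in self.configurations],
            }
        )

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked into an ``(n, k, 2)`` array."""
        return np.stack([c.coords for c in self.configurations])

    def reference_strain(self) -> StrainRecord:
        refs = [r for r in self.strain_table if r.is_reference]
        if len(refs) != 1:
            raise DatasetError(f"expected exactly one reference strain, found {len(refs)}")
        return refs[0]


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def _parse_id(id_string: str) -> tuple[str, str, str, int]:
    parts = id_string.rsplit("_", 3)
    if len(parts) != 4:
        raise ParseError(
            f"ID {id_string!r} does not follow <specimen>_<strain>_<L|R>_<replicate>"
        )
    specimen, strain, side, rep = parts
    try:
        return specimen, strain, side, int(rep)
    except ValueError as exc:
        raise ParseError(f"ID {id_string!r}: replicate {rep!r} is not an integer") from exc


def read_tps(path, metadata: pd.DataFrame | None = None) -> list[LandmarkConfiguration]:
    """Read a TPS file into landmark configurations.

    Each record is ``LM=k``, then ``k`` coordinate lines, then ``ID=...`` and
    optionally ``SCALE=s`` (coordinates are multiplied by the scale factor).
    Metadata is decoded from the ID string, or looked up in ``metadata`` — a
    table indexed by (or containing a column) ``id`` with columns
    ``specimen, strain, side, replicate``.

    The landmark count must be identical across records.
    """
    if metadata is not None and "id" in metadata.columns:
        metadata = metadata.set_index("id")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]

    configs: list[LandmarkConfiguration] = []
    i, n_lines = 0, len(lines)
    while i < n_lines:
        if not lines[i]:
            i += 1
            continue
        if not lines[i].upper().startswith("LM="):
            raise ParseError(f"line {i + 1}: expected LM=, got {lines[i]!r}")
        try:
            k = int(lines[i].split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: malformed LM count") from exc
        i += 1
        pts = []
        while i < n_lines and len(pts) < k:
            if not lines[i] or "=" in lines[i]:
                break
            try:
                x, y = lines[i].split()
                pts.append((float(x), float(y)))
            except ValueError as exc:
                raise ParseError(f"line {i + 1}: bad coordinate line {lines[i]!r}") from exc
            i += 1
        if len(pts) != k:
            raise ParseError(
                f"record ending near line {i}: LM={k} but {len(pts)} coordinate lines"
            )
        id_string, scale = None, None
        while i < n_lines and lines[i] and "=" in lines[i]:
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                id_string = value.strip()
            elif key == "SCALE":
                scale = float(value)
            elif key == "LM":
                break
            i += 1
        if id_string is None:
            raise ParseError(f"record ending near line {i}: missing ID= line")
        coords = np.asarray(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        if metadata is not None:
            try:
                row = metadata.loc[id_string]
            except KeyError as exc:
                raise ParseError(f"ID {id_string!r} missing from sidecar metadata") from exc
            specimen, strain = str(row["specimen"]), str(row["strain"])
            side, rep = str(row["side"]), int(row["replicate"])
        else:
            specimen, strain, side, rep = _parse_id(id_string)
        configs.append(LandmarkConfiguration(specimen, strain, side, rep, coords))

    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise DatasetError(f"mixed landmark counts across TPS records: {sorted(ks)}")
    return configs


def write_tps(path, configs: Sequence[LandmarkConfiguration]) -> None:
    """Write configurations as TPS records (ID encodes the metadata)."""
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.k}\n")
            for x, y in c.coords:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={c.specimen_id}_{c.strain_id}_{c.side}_{c.replicate}\n")


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------

_CSV_COLS = ["specimen", "strain", "side", "replicate", "landmark", "x", "y"]


def read_landmark_csv(path) -> list[LandmarkConfiguration]:
    """Read a long-format landmark CSV (columns: specimen, strain, side,
    replicate, landmark, x, y; landmarks 1-based)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"landmark CSV missing columns {sorted(missing)}")
    configs = []
    for (spec, strain, side, rep), grp in df.groupby(
        ["specimen", "strain", "side", "replicate"], sort=False
    ):
        grp = grp.sort_values("landmark")
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(grp["landmark"].to_numpy(), expected):
            raise ParseError(f"{spec} {side} r{rep}: landmark indices not 1..k")
        configs.append(
            LandmarkConfiguration(
                str(spec), str(strain), str(side), int(rep), grp[["x", "y"]].to_numpy()
            )
        )
    return configs


def write_landmark_csv(path, configs: Sequence[LandmarkConfiguration]) -> None:
    rows = []
    for c in configs:
        for j, (x, y) in enumerate(c.coords, start=1):
            rows.append((c.specimen_id, c.strain_id, c.side, c.replicate, j, x, y))
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Strain table
# ---------------------------------------------------------------------------

def read_strain_table(path) -> list[StrainRecord]:
    """Read the strain covariate CSV.

    Rows with empty/zero ``seg_mb`` and ``n_segments`` are flagged as the
    reference (background) strain.
    """
    df = pd.read_csv(path)
    required = {"strain", "n_mice", "seg_mb", "n_segments", "n_genes"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"strain table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        seg_mb = 0.0 if pd.isna(row["seg_mb"]) else float(row["seg_mb"])
        n_seg = 0 if pd.isna(row["n_segments"]) else int(row["n_segments"])
        n_genes = 0 if pd.isna(row["n_genes"]) else int(row["n_genes"])
        records.append(
            StrainRecord(
                strain_id=str(row["strain"]),
                n_mice=int(row["n_mice"]),
                seg_mb=seg_mb,
                n_segments=n_seg,
                n_genes=n_genes,
                is_reference=(seg_mb == 0.0 and n_seg == 0),
            )
        )
    return records


def write_strain_table(path, records: Sequence[StrainRecord]) -> None:
    df = pd.DataFrame(
        {
            "strain": [r.strain_id for r in records],
            "n_mice": [r.n_mice for r in records],
            "seg_mb": [r.seg_mb if not r.is_reference else np.nan for r in records],
            "n_segments": [r.n_segments if not r.is_reference else np.nan for r in records],
            "n_genes": [r.n_genes if not r.is_reference else np.nan for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Adjacency graph
# ---------------------------------------------------------------------------

def read_adjacency(path, k: int) -> AdjacencyGraph:
    """Read a whitespace-separated edge list of 1-based landmark indices.

    Lines starting with ``#`` are comments.  The resulting graph must cover
    landmarks ``1..k`` and be connected.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected two indices, got {line!r}")
            edges.append((int(parts[0]), int(parts[1])))
    return AdjacencyGraph(k=k, edges=edges)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_text(name: str) -> str:
    return resources.files("morphomod.data").joinpath(name).read_text()


def load_strain_table() -> list[StrainRecord]:
    """The packaged 19-strain study design table (18 congenic strains plus the
    C57BL/6 reference; 362 mice, 46 donor segments in total)."""
    return read_strain_table(_stdio.StringIO(_fixture_text("strain_table.csv")))


def load_template_shape() -> np.ndarray:
    """The packaged 16-landmark hemimandible-like template outline, ``(16, 2)``."""
    df = pd.read_csv(_stdio.StringIO(_fixture_text("template_shape.csv")))
    df = df.sort_values("landmark")
    return df[["x", "y"]].to_numpy(dtype=float)


def load_adjacency(k: int = 16) -> AdjacencyGraph:
    """The packaged default adjacency graph: the outline cycle 1-2-...-16-1."""
    edges = []
    for line in _fixture_text("adjacency_edges.txt").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            a, b = line.split()
            edges.append((int(a), int(b)))
    return AdjacencyGraph(k=k, edges=edges)
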