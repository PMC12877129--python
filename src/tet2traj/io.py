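"""Readers/writers for the formats the pipeline touches, plus configuration.

Formats: Matrix Market triplets with barcode/feature sidecars (single-cell
counts), GMT gene-set files, cohort CSVs, and JSON configuration.  Matrix
Market parsing goes through :mod:`scipy.io`; the line-oriented formats (GMT,
cohort CSV) are parsed here because the pipeline's error contracts (line
numbers, offending sample ids, duplicate warnings) are part of the interface.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .survival import CohortRecord

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SimulationConfig

__all__ = [
    "ExpressionMatrix",
    "GeneModule",
    "AnalysisConfig",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "read_cohort_csv",
    "load_config",
    "write_table",
]


@dataclass
class ExpressionMatrix:
    """A cells-or-samples x genes expression matrix with identifiers.

    ``kind`` is ``"counts"`` (non-negative integers) or ``"normalized"``
    (log-scale, any non-negative floats).  Row and gene identifiers must be
    unique; matching elsewhere in the package is case-sensitive exact string
    match.
    """

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]
    kind: str = "counts"

    def __post_init__(self) -> None:
        if sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.row_ids = [str(r) for r in self.row_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape != (len(self.row_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} row ids and {len(self.gene_ids)} gene ids"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if self.kind not in ("counts", "normalized"):
            raise ValueError(f"kind must be 'counts' or 'normalized', got {self.kind!r}")
        if np.isnan(self.values).any() or (self.values < 0).any():
            raise ValueError("expression values must be finite and non-negative")
        if self.kind == "counts" and not np.array_equal(self.values, np.round(self.values)):
            raise ValueError("counts matrix contains non-integer entries")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_indexer(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indexer()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols].copy(), list(self.row_ids), list(genes), self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class GeneModule:
    """A named gene set (e.g. OXPHOS, WNT_TARGETS) with free-text provenance."""

    name: str
    genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.name!r} has an empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.name!r} has duplicate genes")

    def shared_genes(self, matrix: ExpressionMatrix) -> list[str]:
        present = set(matrix.gene_ids)
        return [g for g in self.genes if g in present]


# ---------------------------------------------------------------------------
# Matrix Market triplet
# ---------------------------------------------------------------------------

def read_mtx_triplet(directory: str | Path) -> ExpressionMatrix:
    """Read ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` as counts.

    The returned matrix is always oriented rows = cells, columns = genes; the
    on-disk orientation is inferred from the sidecar lengths (the 10x
    convention stores genes x cells).
    """
    directory = Path(directory)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing {name} in {directory}")
    mat = spio.mmread(directory / "matrix.mtx")
    mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    barcodes = _read_sidecar(directory / "barcodes.tsv")
    features = _read_sidecar(directory / "features.tsv")
    nb, nf = len(barcodes), len(features)
    if mat.shape == (nb, nf):
        pass
    elif mat.shape == (nf, nb):
        mat = mat.T
    else:
        bad = "barcodes.tsv" if nb not in mat.shape else "features.tsv"
        raise ValueError(
            f"{bad}: sidecar lengths (barcodes={nb}, features={nf}) do not match "
            f"matrix.mtx dimensions {mat.shape}"
        )
    if not np.array_equal(mat, np.round(mat)):
        raise ValueError("matrix.mtx contains non-integer entries; expected raw counts")
    return ExpressionMatrix(mat, barcodes, features, kind="counts")


def _read_sidecar(path: Path) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"{path.name} is empty")
    return ids


def write_mtx_triplet(matrix: ExpressionMatrix, directory: str | Path) -> None:
    """Write a counts matrix as matrix.mtx + barcodes.tsv + features.tsv."""
    if matrix.kind != "counts":
        raise ValueError("only counts matrices are written as Matrix Market triplets")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.csr_matrix(matrix.values.astype(int)))
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.row_ids))
    (directory / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneModule]:
    """Parse a tab-separated GMT file (name, description, gene, gene, ...)."""
    modules: list[GeneModule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has {len(fields)} fields; GMT needs >= 3")
            name, provenance, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(f"{path}: line {lineno} ({name}): duplicate genes removed")
            modules.append(GeneModule(name, tuple(deduped), provenance))
    return modules


def write_gmt(modules: Sequence[GeneModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in modules:
            fh.write("\t".join([m.name, m.provenance or "-", *m.genes]) + "\n")


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

_COHORT_REQUIRED = ("sample_id", "nuclear_fraction", "stage", "time", "event")


def read_cohort_csv(path: str | Path) -> list[CohortRecord]:
    """Read an IHC cohort CSV into validated :class:`CohortRecord` objects.

    Required columns: sample_id, nuclear_fraction, stage, time, event.  An
    optional ``stage_tnm`` column and any further columns (e.g. a 5mC score)
    are carried through unmodified.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; required: {list(_COHORT_REQUIRED)}")
    extra_cols = [c for c in df.columns if c not in _COHORT_REQUIRED and c != "stage_tnm"]
    records = []
    for _, row in df.iterrows():
        records.append(
            CohortRecord(
                sample_id=str(row["sample_id"]),
                nuclear_fraction=float(row["nuclear_fraction"]),
                time=float(row["time"]),
                event=int(row["event"]),
                stage_dukes=None if pd.isna(row["stage"]) else str(row["stage"]),
                stage_tnm=(
                    None
                    if "stage_tnm" not in df.columns or pd.isna(row["stage_tnm"])
                    else str(row["stage_tnm"])
                ),
                extra={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_cohort_csv(records: Sequence[CohortRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "nuclear_fraction": r.nuclear_fraction,
            "category": r.category,
            "stage": r.stage_dukes,
            "stage_tnm": r.stage_tnm,
            "time": r.time,
            "event": r.event,
            **r.extra,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Resolved pipeline configuration with defaults filled in."""

    simulation: "SimulationConfig"
    n_bins: int = 100
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    r2_min: float = 0.3
    tie_eps: float = 1.0
    window: tuple[int, int] = (36, 75)
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0 < self.r2_min <= 1:
            raise ValueError(f"r2_min must be in (0, 1], got {self.r2_min}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.n_bins):
            raise ValueError(f"window {self.window} must lie within 1..{self.n_bins}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def _check_keys(given: dict, allowed: Sequence[str], context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown configuration key {context}{key!r}{suggestion}")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a JSON configuration; unknown keys are rejected.

    An empty JSON object yields the full default configuration.  The
    ``simulation`` sub-object maps onto :class:`~tet2traj.simulate.SimulationConfig`.
    """
    from .simulate import SimulationConfig  # deferred: simulate imports this module

    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a JSON object")
    top_allowed = [f.name for f in dataclasses.fields(AnalysisConfig)]
    _check_keys(raw, top_allowed, "")
    sim_raw = raw.pop("simulation", {})
    sim_allowed = [f.name for f in dataclasses.fields(SimulationConfig)]
    _check_keys(sim_raw, sim_allowed, "simulation.")
    if "module_params" in sim_raw:
        from .simulate import ModuleActivationParams

        sim_raw["module_params"] = tuple(
            ModuleActivationParams(**p) for p in sim_raw["module_params"]
        )
    if "window" in raw:
        raw["window"] = tuple(raw["window"])
    if "conditions" in sim_raw:
        sim_raw["conditions"] = tuple(sim_raw["conditions"])
    if "timepoint_mixture" in sim_raw:
        sim_raw["timepoint_mixture"] = {k: tuple(v) for k, v in sim_raw["timepoint_mixture"].items()}
    simulation = SimulationConfig(**sim_raw)
    return AnalysisConfig(simulation=simulation, **raw)


def config_hash(config) -> str:
    """Short stable hash of a (dataclass) configuration, for provenance lines."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config=None) -> None:
    """Write a TSV with a leading provenance comment (tool version, config hash)."""
    from . import __version__

    tag = f"# tet2traj {__version__}"
    if config is not None:
        tag += f" config_sha={config_hash(config)}"
    with open(path, "w") as fh:
        fh.write(tag + "\n")
        df.to_csv(fh, sep="\t", index=False)
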