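"""Readers and writers for the formats the pipeline touches.

TPS landmark files (the output of the classic 2D digitizing tools),
Newick trees (single- and multi-tree files), CSV measurement/factor
tables, and JSON result reports.  Also the categorical codings used by
the analysis: Gosner-stage collapsing and species-name normalization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .tree import Phylogeny

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

LARVAL_GUILDS = ("lentic", "lotic", "endotrophic", "semiterrestrial")
ADULT_GUILDS = ("semi-aquatic", "torrential", "saxicolous", "terrestrial")
STAGE_CLASSES = ("limb_bud", "autopodium", "tarsal")


class TpsFormatError(ValueError):
    """Malformed TPS file (bad coordinates or inconsistent landmark counts)."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration.

    ``coords`` is a (k, 2) array in image units (SCALE already applied,
    y-up mathematical convention).  ``stage`` is the Gosner stage, when
    recorded (26-41 for the larval data handled here).
    """

    specimen_id: str
    coords: np.ndarray
    species: str | None = None
    scale: float | None = None
    stage: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class MeasurementTable:
    """Species-by-measurement table of linear measurements in mm.

    ``svl`` (snout-vent length) is carried separately from the shape
    measurements and is never missing; measurement cells may be NaN.
    """

    svl: pd.Series
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.svl = pd.Series(self.svl, dtype=float)
        self.values = self.values.astype(float)
        if not self.svl.index.equals(self.values.index):
            raise ValueError("svl and values must share the same species index")
        if self.values.columns.duplicated().any():
            raise ValueError("measurement names must be unique")
        if self.svl.isna().any():
            raise ValueError("svl must not be missing")
        observed = self.values.to_numpy()
        if np.any(observed[~np.isnan(observed)] <= 0):
            raise ValueError("non-missing measurements must be strictly positive")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(self.svl.copy(), self.values.copy())


# --------------------------------------------------------------------------
# TPS landmarks
# --------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    Accepts ``LM=`` records with optional ``ID=``, ``SCALE=``, ``SPECIES=``
    and ``STAGE=`` keys; ``IMAGE=`` and ``COMMENT=`` lines are ignored.
    ``SCALE`` is applied multiplicatively to the stored coordinates.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    coords: list[tuple[float, float]] | None = None
    meta: dict[str, Any] = {}
    expect = 0

    def flush(lineno: int) -> None:
        nonlocal coords, meta
        if coords is None:
            return
        if len(coords) != expect:
            raise TpsFormatError(
                f"{path}: record {meta.get('ID', len(configs))} declares LM={expect} "
                f"but has {len(coords)} coordinate lines (near line {lineno})"
            )
        arr = np.asarray(coords, dtype=float)
        scale = meta.get("SCALE")
        if scale is not None:
            arr = arr * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(meta.get("ID", f"rec{len(configs)}")),
                coords=arr,
                species=meta.get("SPECIES"),
                scale=scale,
                stage=meta.get("STAGE"),
            )
        )
        coords, meta = None, {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            if sep and key.isalpha() and key.isupper():
                if key == "LM":
                    flush(lineno)
                    expect = int(value)
                    coords = []
                elif key == "SCALE":
                    meta["SCALE"] = float(value)
                elif key == "ID":
                    meta["ID"] = value.strip()
                elif key == "SPECIES":
                    meta["SPECIES"] = value.strip()
                elif key == "STAGE":
                    meta["STAGE"] = int(value)
                # IMAGE=, COMMENT=, etc. are digitizer metadata: skipped
                continue
            if coords is None:
                raise TpsFormatError(f"{path}:{lineno}: coordinate outside a record")
            parts = line.split()
            if len(parts) != 2:
                raise TpsFormatError(f"{path}:{lineno}: expected 'x y', got {line!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise TpsFormatError(
                    f"{path}:{lineno}: non-numeric coordinate {line!r}"
                ) from None
    flush(lineno=-1)

    counts = {c.n_landmarks for c in configs}
    if len(counts) > 1:
        bad = next(c for c in configs if c.n_landmarks != configs[0].n_landmarks)
        raise TpsFormatError(
            f"{path}: unequal landmark counts across records "
            f"(record {bad.specimen_id!r} has {bad.n_landmarks}, "
            f"first record has {configs[0].n_landmarks})"
        )
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file (coordinates at 6 decimals)."""
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.n_landmarks}\n")
            for x, y in c.coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if c.species is not None:
                fh.write(f"SPECIES={c.species}\n")
            if c.stage is not None:
                fh.write(f"STAGE={c.stage}\n")
            fh.write(f"ID={c.specimen_id}\n")


# --------------------------------------------------------------------------
# Newick trees
# --------------------------------------------------------------------------

def _check_ultrametric(tree: Phylogeny, source: str) -> None:
    if not tree.is_ultrametric():
        d = tree.depths[tree.tip_indices]
        warnings.warn(
            f"{source}: tree is not ultrametric "
            f"(tip depth range {d.min():.6g}..{d.max():.6g}); "
            "node times are computed from the root anyway",
            stacklevel=3,
        )


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single-tree Newick file; warns when not ultrametric."""
    trees = read_newick_trees(path)
    if len(trees) != 1:
        raise ValueError(f"{path}: expected 1 tree, found {len(trees)}")
    return trees[0]


def read_newick_trees(path: str | Path) -> list[Phylogeny]:
    """Read a (possibly multi-tree) Newick file, preserving file order."""
    tree_list = dendropy.TreeList.get(path=str(path), schema="newick")
    out = []
    for i, t in enumerate(tree_list):
        phylo = Phylogeny.from_dendropy(t)
        _check_ultrametric(phylo, f"{path}[{i}]")
        out.append(phylo)
    return out


def write_newick(trees: Phylogeny | Sequence[Phylogeny], path: str | Path) -> None:
    if isinstance(trees, Phylogeny):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# --------------------------------------------------------------------------
# CSV tables
# --------------------------------------------------------------------------

def read_measurements(path: str | Path, svl_column: str = "svl") -> MeasurementTable:
    """Read a measurement CSV (first column = species; empty/NA = missing)."""
    df = pd.read_csv(path, index_col=0)
    df.index = [normalize_name(s) for s in df.index]
    if svl_column not in df.columns:
        raise ValueError(f"{path}: missing required column {svl_column!r}")
    return MeasurementTable(df[svl_column], df.drop(columns=[svl_column]))


def write_measurements(
    table: MeasurementTable, path: str | Path, svl_column: str = "svl"
) -> None:
    out = table.values.copy()
    out.insert(0, svl_column, table.svl)
    out.to_csv(path, index_label="species")


def read_factors(path: str | Path) -> pd.DataFrame:
    """Read the species factor table (family, genus, guilds, stage class).

    Guild and stage-class labels are validated against their closed sets.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = [normalize_name(s) for s in df.index]
    if df.index.duplicated().any():
        raise ValueError(f"{path}: one row per species required")
    closed = {
        "larval_guild": LARVAL_GUILDS,
        "adult_guild": ADULT_GUILDS,
        "stage_class": STAGE_CLASSES,
    }
    for col, allowed in closed.items():
        if col in df.columns:
            bad = set(df[col].dropna()) - set(allowed)
            if bad:
                raise ValueError(f"{path}: invalid {col} labels {sorted(bad)}")
    return df


# --------------------------------------------------------------------------
# Categorical codings
# --------------------------------------------------------------------------

def collapse_stage(stage: int) -> str:
    """Collapse a Gosner stage (26-41) into its developmental-period class.

    Limb bud: 26-30; autopodium development: 31-37; tarsal tubercle
    differentiation: 38-41.
    """
    stage = int(stage)
    if not 26 <= stage <= 41:
        raise ValueError(f"Gosner stage {stage} outside the larval range [26, 41]")
    if stage <= 30:
        return "limb_bud"
    if stage <= 37:
        return "autopodium"
    return "tarsal"


def normalize_name(name: str) -> str:
    """Normalize a species name for matching: spaces -> underscores."""
    return "_".join(str(name).strip().split())


def match_species(
    table_species: Sequence[str], tree_labels: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Match species between a data table and a tree after name normalization.

    Returns (matched, dropped-from-table).  Drops are logged: tree-based
    stages run on the intersection while morphospace/decoupling stages
    keep the full table.
    """
    tree_set = {normalize_name(s) for s in tree_labels}
    matched = [s for s in table_species if normalize_name(s) in tree_set]
    dropped = [s for s in table_species if normalize_name(s) not in tree_set]
    if dropped:
        log.info(
            "species matching: %d of %d table species on tree; dropped %d (%s%s)",
            len(matched),
            len(table_species),
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    return matched, dropped


# --------------------------------------------------------------------------
# JSON reports
# --------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "type": type(obj).__name__,
            **{
                f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "index": [str(i) for i in obj.index],
            "columns": [str(c) for c in obj.columns],
            "data": obj.to_numpy().tolist(),
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


_REPRO_KEYS = ("seed", "nperm", "nsim", "n_iter", "iterations")


def write_report(results: Any, path: str | Path, seed: int | None = None) -> None:
    """Serialize a result object to JSON with a reproducibility block.

    Numbers are written at full double precision; seeds and iteration
    counts found on the object (or passed explicitly) are collected under
    ``reproducibility``.
    """
    payload = _jsonable(results)
    repro: dict[str, Any] = {}
    if isinstance(payload, dict):
        for key in _REPRO_KEYS:
            if key in payload and payload[key] is not None:
                repro[key] = payload[key]
    if seed is not None:
        repro["seed"] = seed
    doc = {
        "schema_version": SCHEMA_VERSION,
        "reproducibility": repro,
        "results": payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


@dataclass
class ReportEnvelope:
    """Convenience view of a written report file."""

    schema_version: str
    reproducibility: dict[str, Any] = field(default_factory=dict)
    results: Any = None
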