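"""Reading, validating and writing the three community data tables.

Three delimited-text inputs drive the pipeline: an interaction edge list
(``plant, pollinator[, weight]``), a stigma pollen table (either long form,
one row per stigma x pollen-donor species, or pre-summarized with
``cp, hp, hp_diversity`` per stigma), and a per-species floral-trait table.
Delimiters (comma or tab) are auto-detected; species labels are opaque,
case-sensitive strings matched exactly after whitespace trimming.

Empty stigmas (no pollen at all) are retained at load and excluded at
analysis time.  An ``UNKNOWN`` pollen donor counts toward HP grains and as
one donor species.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .summaries import flower_area

__all__ = [
    "SchemaError",
    "Dataset",
    "LoadReport",
    "read_interactions",
    "read_stigma_table",
    "read_traits",
    "validate_dataset",
    "write_report",
]


class SchemaError(ValueError):
    """An input table is missing required columns or violates an invariant."""


def _read_delimited(path) -> pd.DataFrame:
    """Read CSV/TSV with delimiter sniffing and whitespace-trimmed strings."""
    path = Path(path)
    sample = path.read_text().splitlines()
    if not sample:
        raise SchemaError(f"{path}: empty file")
    delim = "\t" if sample[0].count("\t") >= sample[0].count(",") else ","
    df = pd.read_csv(path, sep=delim, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for c in df.columns:
        df[c] = df[c].str.strip()
    return df


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


@dataclass(frozen=True)
class LoadReport:
    """Counts reported after loading an interaction edge list."""

    n_edges: int
    n_plants: int
    n_pollinators: int

    def __str__(self) -> str:
        return (
            f"{self.n_edges} unique links between {self.n_plants} plant species "
            f"and {self.n_pollinators} pollinator species"
        )


def read_interactions(path) -> tuple[pd.DataFrame, LoadReport]:
    """Read a plant-pollinator edge list; duplicates are summed.

    Columns ``plant, pollinator`` required; ``weight`` defaults to 1.
    Returns the deduplicated edges and a :class:`LoadReport` with the
    distinct-species and unique-link counts.
    """
    df = _read_delimited(path)
    _require(df, ["plant", "pollinator"], path)
    if "weight" in df.columns:
        weights = pd.to_numeric(df["weight"], errors="coerce")
        bad = weights.isna() | (weights < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise SchemaError(f"{path}: invalid or negative weight at line {row}")
    else:
        weights = pd.Series(1.0, index=df.index)
    edges = (
        pd.DataFrame(
            {"plant": df["plant"], "pollinator": df["pollinator"], "weight": weights}
        )
        .groupby(["plant", "pollinator"], as_index=False, sort=True)["weight"]
        .sum()
    )
    report = LoadReport(
        n_edges=len(edges),
        n_plants=int(edges["plant"].nunique()),
        n_pollinators=int(edges["pollinator"].nunique()),
    )
    return edges, report


def read_stigma_table(path, format: Literal["long", "summary"] = "summary") -> pd.DataFrame:
    """Read stigma pollen loads in long or summary form.

    Long form: one row per (stigma, donor species) with columns
    ``stigma_id, focal_species, donor_species, grains``; rows are
    aggregated per stigma into CP (grains from the focal species), HP
    (grains from all other donors) and HP diversity (distinct non-focal
    donors with grains > 0).  Summary form carries ``stigma_id, species,
    cp, hp, hp_diversity`` directly.  Invariants (counts >= 0 integers,
    hp_diversity <= hp, hp_diversity = 0 iff hp = 0) are enforced.
    """
    df = _read_delimited(path)
    if format == "long":
        _require(df, ["stigma_id", "focal_species", "donor_species", "grains"], path)
        grains = pd.to_numeric(df["grains"], errors="coerce")
        if grains.isna().any() or (grains < 0).any() or (grains % 1 != 0).any():
            raise SchemaError(f"{path}: grains must be non-negative integers")
        df = df.assign(grains=grains.astype(int))
        dup = df.duplicated(["focal_species", "stigma_id", "donor_species"])
        if dup.any():
            raise SchemaError(
                f"{path}: duplicate (stigma, donor) rows within a focal species"
            )
        rows = []
        for (sid, sp), grp in df.groupby(["stigma_id", "focal_species"], sort=True):
            own = grp["donor_species"] == sp
            hp_rows = grp.loc[~own]
            rows.append(
                {
                    "stigma_id": sid,
                    "species": sp,
                    "cp": int(grp.loc[own, "grains"].sum()),
                    "hp": int(hp_rows["grains"].sum()),
                    "hp_diversity": int((hp_rows["grains"] > 0).sum()),
                }
            )
        out = pd.DataFrame(rows, columns=["stigma_id", "species", "cp", "hp", "hp_diversity"])
    elif format == "summary":
        _require(df, ["stigma_id", "species", "cp", "hp", "hp_diversity"], path)
        out = df.copy()
        for c in ("cp", "hp", "hp_diversity"):
            vals = pd.to_numeric(out[c], errors="coerce")
            if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
                raise SchemaError(f"{path}: column {c!r} must be non-negative integers")
            out[c] = vals.astype(int)
        bad = out["hp_diversity"] > out["hp"]
        if bad.any():
            raise SchemaError(
                f"{path}: hp_diversity exceeds hp for stigma(s) "
                f"{list(out.loc[bad, 'stigma_id'].head())}"
            )
        bad = (out["hp_diversity"] == 0) != (out["hp"] == 0)
        if bad.any():
            raise SchemaError(
                f"{path}: hp_diversity must be zero exactly when hp is zero; "
                f"violated for stigma(s) {list(out.loc[bad, 'stigma_id'].head())}"
            )
    else:
        raise ValueError(f"unknown stigma table format {format!r}; use 'long' or 'summary'")
    return out.sort_values(["species", "stigma_id"]).reset_index(drop=True)


_SYMMETRY = {"R": "radial", "B": "bilateral", "radial": "radial", "bilateral": "bilateral"}
_DIM_COLS = ["r", "L", "W", "l", "w", "B_dim", "D"]


def read_traits(path) -> pd.DataFrame:
    """Read the per-species floral trait table.

    Requires ``species`` and ``symmetry`` ({R, B, radial, bilateral});
    either ``flower_size`` (mm^2) directly, or ``shape_class`` plus the
    linear dimensions that shape requires (``r, L, W, l, w, B_dim, D`` in
    mm; ``B_dim`` is the tube bore diameter), from which the area is
    computed.
    """
    df = _read_delimited(path)
    _require(df, ["species", "symmetry"], path)
    bad = ~df["symmetry"].isin(_SYMMETRY)
    if bad.any():
        raise SchemaError(
            f"{path}: unknown symmetry code(s) {sorted(df.loc[bad, 'symmetry'].unique())}; "
            f"legal codes: {sorted(set(_SYMMETRY))}"
        )
    out = pd.DataFrame(
        {"species": df["species"], "symmetry": df["symmetry"].map(_SYMMETRY)}
    )
    if "flower_size" in df.columns and df["flower_size"].notna().all():
        sizes = pd.to_numeric(df["flower_size"], errors="coerce")
        if sizes.isna().any() or (sizes <= 0).any():
            raise SchemaError(f"{path}: flower_size must be positive")
        out["flower_size"] = sizes.astype(float)
    elif "shape_class" in df.columns:
        sizes = []
        for _, row in df.iterrows():
            dims = {}
            for c in _DIM_COLS:
                if c in df.columns and isinstance(row.get(c), str) and row[c] != "":
                    key = "B" if c == "B_dim" else c
                    dims[key] = float(row[c])
            sizes.append(flower_area(row["shape_class"], **dims))
        out["flower_size"] = sizes
    else:
        raise SchemaError(
            f"{path}: provide either a flower_size column or shape_class + dimensions"
        )
    return out.set_index("species")


@dataclass
class Dataset:
    """The three joined community tables plus provenance notes."""

    edges: pd.DataFrame | None = None
    stigmas: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def validate_dataset(dataset: Dataset) -> dict:
    """Cross-table consistency report (warnings only, never errors).

    Lists species present in the stigma table but absent from the traits
    or the network, the number of empty stigmas (excluded-from-analysis
    candidates), and per-species stigma counts.
    """
    report: dict = {"warnings": []}
    if dataset.stigmas is not None:
        st = dataset.stigmas
        species = set(st["species"].unique())
        report["n_stigmas"] = len(st)
        report["stigmas_per_species"] = st.groupby("species").size().to_dict()
        n_empty = int(((st["cp"] + st["hp"]) == 0).sum())
        report["n_empty"] = n_empty
        report["note_empty"] = f"{n_empty} excluded-from-analysis candidates"
        if dataset.traits is not None:
            missing = sorted(species - set(dataset.traits.index))
            for sp in missing:
                report["warnings"].append(f"species {sp!r} in stigma table but not in traits")
        if dataset.edges is not None:
            missing = sorted(species - set(dataset.edges["plant"].unique()))
            for sp in missing:
                report["warnings"].append(f"species {sp!r} in stigma table but not in network")
    return report


def write_report(results: dict[str, pd.DataFrame], out_dir, metadata: dict | None = None) -> list[Path]:
    """Write result tables as CSV plus a run-metadata file.

    ``results`` maps table names to DataFrames; each is written as
    ``<name>.csv`` (headers-only when empty).  ``metadata`` (config, seed,
    software version) is written to ``run_metadata.txt``.  Reruns with the
    same inputs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=not isinstance(df.index, pd.RangeIndex))
        written.append(p)
    meta = dict(metadata or {})
    from . import __version__

    meta.setdefault("pollennet_version", __version__)
    p = out / "run_metadata.txt"
    p.write_text("".join(f"{k} = {v}\n" for k, v in sorted(meta.items())))
    written.append(p)
    return written
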