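"""Readers and writers for the package's on-disk formats.

Expression matrices travel as TSV/CSV (first column gene symbol, remaining
columns samples), gene sets as GMT, labels and survival tables as CSV, and
slide bags as an HDF5 container with /patches and /cells groups plus a JSON
sidecar for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .evaluation import SurvivalRecord
from .labels import SubtypeLabelRecord, SubtypeScoreRecord
from .tissue import CellRecord, PatchRecord, SlideBag, SlideGeometry

BAG_FORMAT_VERSION = 1


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, unit: str = "TPM",
                    subset: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV; errors name offending columns/lines."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate sample column(s): {dupes}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene row(s): {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        line = df.index.get_loc(gene) + 2  # header is line 1
        raise ValueError(f"non-numeric cell at gene {gene!r} (line {line})")
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        raise ValueError(f"missing value in row for gene {gene!r}")
    return ExpressionMatrix.from_frame(numeric, unit=unit, subset=subset)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene")


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Two-column TSV (symbol, length-bp) -> Series indexed by symbol."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, names=["gene", "length"],
                     comment="#")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene in lengths table")
    lengths = pd.to_numeric(df["length"], errors="coerce")
    if lengths.isna().any():
        raise ValueError(f"non-numeric length at line {int(lengths.isna().idxmax()) + 1}")
    return pd.Series(lengths.to_numpy(), index=df["gene"].tolist())


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> symbol..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def labels_to_frame(labels: Sequence[SubtypeLabelRecord],
                    scores: Sequence[SubtypeScoreRecord]) -> pd.DataFrame:
    by_id = {s.sample_id: s for s in scores}
    rows = []
    for rec in labels:
        s = by_id[rec.sample_id]
        rows.append({
            "sample_id": rec.sample_id,
            "es_classical": s.es_classical,
            "es_basal": s.es_basal,
            "score": s.score,
            "z": s.z,
            "label": rec.label,
            "confidence": rec.confidence,
            "gata6_tpm": rec.gata6_tpm,
            "gata6_tertile": rec.gata6_tertile,
        })
    return pd.DataFrame(rows)


def write_labels(labels: Sequence[SubtypeLabelRecord],
                 scores: Sequence[SubtypeScoreRecord], path: str | Path) -> None:
    labels_to_frame(labels, scores).to_csv(path, index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """CSV with columns sample_id, time_months, event, group."""
    df = pd.read_csv(path)
    required = {"sample_id", "time_months", "event", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing column(s): {sorted(missing)}")
    return [
        SurvivalRecord(str(r.sample_id), float(r.time_months), int(r.event), str(r.group))
        for r in df.itertuples()
    ]


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Slide-bag HDF5 container
# ---------------------------------------------------------------------------

def write_bag(bag: SlideBag, path: str | Path, sidecar: bool = True) -> None:
    """HDF5 layout: /patches {embeddings, grid}, /cells {embeddings, centroids,
    types, patch_assignment}, with slide attributes on the root group."""
    cell_index = {c.cell_id: i for i, c in enumerate(bag.cells)}
    assignment = np.full(len(bag.cells), -1, dtype=np.int64)
    for pi, patch in enumerate(bag.patches):
        for cid in patch.cell_ids:
            assignment[cell_index[cid]] = pi
    with h5py.File(path, "w") as f:
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["width_px"] = bag.geometry.width_px
        f.attrs["height_px"] = bag.geometry.height_px
        f.attrs["patch_mag_factor"] = bag.geometry.patch_mag_factor
        f.attrs["mpp"] = bag.geometry.mpp if bag.geometry.mpp is not None else -1.0
        f.attrs["label"] = bag.label or ""
        f.attrs["n_discarded_cells"] = bag.n_discarded_cells
        f.attrs["format_version"] = BAG_FORMAT_VERSION
        g = f.create_group("patches")
        g.create_dataset("embeddings",
                         data=np.stack([p.embedding for p in bag.patches])
                         if bag.patches else np.zeros((0, 0)))
        g.create_dataset("grid", data=np.array(
            [(p.grid_col, p.grid_row) for p in bag.patches], dtype=np.int64
        ).reshape(-1, 2))
        g.create_dataset("origin", data=np.array(
            [(p.origin_x, p.origin_y) for p in bag.patches], dtype=np.int64
        ).reshape(-1, 2))
        c = f.create_group("cells")
        c.create_dataset("ids", data=[x.cell_id for x in bag.cells])
        c.create_dataset("embeddings",
                         data=np.stack([x.embedding for x in bag.cells])
                         if bag.cells else np.zeros((0, 0)))
        c.create_dataset("centroids", data=np.array(
            [(x.centroid_x, x.centroid_y) for x in bag.cells]).reshape(-1, 2))
        c.create_dataset("types", data=[x.cell_type for x in bag.cells])
        c.create_dataset("patch_assignment", data=assignment)
    if sidecar:
        meta = {
            "slide_id": bag.slide_id,
            "format_version": BAG_FORMAT_VERSION,
            "n_patches": len(bag.patches),
            "n_cells": len(bag.cells),
            "label": bag.label,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_bag(path: str | Path) -> SlideBag:
    with h5py.File(path, "r") as f:
        mpp = float(f.attrs["mpp"])
        geometry = SlideGeometry(
            width_px=int(f.attrs["width_px"]),
            height_px=int(f.attrs["height_px"]),
            mpp=None if mpp < 0 else mpp,
            patch_mag_factor=int(f.attrs["patch_mag_factor"]),
        )
        grid = f["patches/grid"][...]
        origin = f["patches/origin"][...]
        pembs = f["patches/embeddings"][...]
        patches = [
            PatchRecord(int(grid[i, 0]), int(grid[i, 1]),
                        int(origin[i, 0]), int(origin[i, 1]), embedding=pembs[i])
            for i in range(grid.shape[0])
        ]
        ids = [x.decode() for x in f["cells/ids"][...]]
        cembs = f["cells/embeddings"][...]
        cents = f["cells/centroids"][...]
        types = [x.decode() for x in f["cells/types"][...]]
        assignment = f["cells/patch_assignment"][...]
        cells = [
            CellRecord(ids[i], float(cents[i, 0]), float(cents[i, 1]),
                       cembs[i], types[i])
            for i in range(len(ids))
        ]
        for i, pi in enumerate(assignment):
            if pi >= 0:
                patches[pi].cell_ids.append(ids[i])
        label = f.attrs["label"] or None
        return SlideBag(
            slide_id=str(f.attrs["slide_id"]),
            geometry=geometry,
            patches=patches,
            cells=cells,
            label=str(label) if label else None,
            n_discarded_cells=int(f.attrs["n_discarded_cells"]),
        )


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
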