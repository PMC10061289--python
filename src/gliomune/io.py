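"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (genes as rows, first column the gene id,
FPKM values), gene sets as GMT, clinical tables as CSV, and volumes/masks as
NIfTI-1 — the formats a transcriptomics/radiomics practitioner already has.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_volume_mask",
    "write_volume",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional role tag per set.

    Roles tag cell types with the semantic labels the composite pro-/antitumor
    scores need (e.g. ``"MDSC"``, ``"Macrophage M2"``) or mark pathway sets.
    """

    sets: dict[str, frozenset[str]]
    roles: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, then one gene per field)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: GMT line needs a name, a "
                    f"description and at least one gene (got {len(fields)} fields)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}, line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}, line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, collection.roles.get(name, "na"))
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples FPKM matrix from TSV (column 1 = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a 'sample_id' column")
    return df.set_index("sample_id")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def write_volume(
    array: np.ndarray, spacing: tuple[float, float, float], path: str | Path
) -> None:
    """Write a 3D array as NIfTI-1 with a diagonal affine from the spacing."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))


def read_volume_mask(
    image_path: str | Path, mask_path: str | Path
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Load an image/mask pair; returns (image, binary mask, voxel spacing in mm).

    The mask is binarized (> 0). Grids must match in shape; the image header's
    zooms define the spacing.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    image = np.asarray(img.dataobj, dtype=np.float64)
    mask = np.asarray(msk.dataobj) > 0
    if image.shape != mask.shape:
        raise ValueError(
            f"image/mask shape mismatch: image {image.shape} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError(f"mask {mask_path} is empty")
    if not np.isfinite(image).all():
        raise ValueError(f"non-finite intensities in {image_path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return image, mask, spacing
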