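"""Score-space cytology: ROI spectra, PCA scores, and class separation.

Analyst-placed 10x10 pixel ROIs are cut from a hyperspectral cube, averaged
into one spectrum per cell, and projected onto the eigenvectors of the
across-cell covariance matrix.  Each principal-component score is the inner
product of a mean-centred cell spectrum with a unit eigenvector; PC1 acts
as a comprehensive brightness/stain indicator while PC2-PC3 carry the
class-separating contrast between normal, non-normal (reactive) and
malignant cells.  Reporting stays unsupervised — scatter plots, centroids
and a silhouette separation index — with a nearest-centroid assignment
offered as a convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorimetry as cm
from .reconstruction import HyperCube

__all__ = [
    "CLASS_LABELS",
    "CellRecord",
    "ScoreTable",
    "extract_roi",
    "mean_spectrum",
    "cells_from_cube",
    "pca_scores",
    "score_space_report",
    "nearest_centroid_assign",
]

CLASS_LABELS = ("malignant", "non_normal", "normal")  # alphabetical tie order


@dataclass
class CellRecord:
    """One surveyed cell: ROI location, class, pixel spectra and their mean."""

    cell_id: str
    label: str
    compartment: str  # nucleus | cytoplasm
    roi_origin: tuple  # (row, col), 0-based top-left
    roi_size: int
    pixel_spectra: np.ndarray  # (size^2, 401)
    mean_spectrum: np.ndarray = None

    def __post_init__(self):
        if self.label not in ("normal", "non_normal", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.compartment not in ("nucleus", "cytoplasm"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        self.pixel_spectra = cm.validate_spectrum(self.pixel_spectra, "pixel_spectra")
        if self.pixel_spectra.shape[0] != self.roi_size**2:
            raise ValueError(
                f"expected {self.roi_size**2} pixel spectra for a "
                f"{self.roi_size}x{self.roi_size} ROI, got {self.pixel_spectra.shape[0]}"
            )
        if self.mean_spectrum is None:
            self.mean_spectrum = self.pixel_spectra.mean(axis=0)


def extract_roi(cube: HyperCube, origin, size: int = 10) -> np.ndarray:
    """Row-major flattened spectra of a size x size window; (size^2, 401)."""
    row, col = int(origin[0]), int(origin[1])
    if row < 0 or col < 0 or row + size > cube.height or col + size > cube.width:
        raise ValueError(
            f"ROI origin ({row}, {col}) size {size} falls outside the "
            f"{cube.height}x{cube.width} cube"
        )
    window = cube.spectra[row : row + size, col : col + size]
    return window.reshape(size * size, -1).astype(float)


def mean_spectrum(pixel_spectra) -> np.ndarray:
    """Per-wavelength arithmetic mean of a stack of pixel spectra."""
    arr = np.atleast_2d(cm.validate_spectrum(pixel_spectra, "pixel_spectra"))
    if arr.shape[0] == 0:
        raise ValueError("cannot average an empty set of pixel spectra")
    return arr.mean(axis=0)


def cells_from_cube(cube: HyperCube, annotations) -> list[CellRecord]:
    """Build CellRecords from a cube and ROI annotation dicts/rows.

    Annotations need cell_id, label, compartment, row, col, size fields
    (e.g. the dicts emitted by the synthetic scene generator or rows of an
    annotations CSV).
    """
    records = []
    for ann in annotations:
        size = int(ann["size"])
        pix = extract_roi(cube, (ann["row"], ann["col"]), size)
        records.append(
            CellRecord(
                cell_id=str(ann["cell_id"]),
                label=str(ann["label"]),
                compartment=str(ann["compartment"]),
                roi_origin=(int(ann["row"]), int(ann["col"])),
                roi_size=size,
                pixel_spectra=pix,
            )
        )
    return records


@dataclass
class ScoreTable:
    """Principal-component scores of cell mean spectra."""

    cell_ids: list
    labels: list
    scores: np.ndarray          # (n, k)
    explained_ratio: np.ndarray  # (k,)
    loadings: np.ndarray         # (k, 401) unit eigenvectors

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])]
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pca_scores(mean_spectra, n_components: int, cell_ids=None, labels=None) -> ScoreTable:
    """PCA scores of cell mean spectra via the across-cell covariance matrix.

    Spectra are centred on the across-cell mean at each wavelength; scores
    are inner products with unit-norm eigenvectors ordered by decreasing
    eigenvalue.  Sign convention: each eigenvector's largest-magnitude
    element is positive.
    """
    arr = np.atleast_2d(cm.validate_spectrum(mean_spectra, "mean_spectra"))
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells for PCA")
    if n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds n-1={n - 1}")
    from .reconstruction import fit_spectral_basis

    basis = fit_spectral_basis(arr, n_components=n_components)
    scores = basis.scores(arr)
    if cell_ids is None:
        cell_ids = [f"cell_{i:03d}" for i in range(n)]
    if labels is None:
        labels = ["unlabeled"] * n
    return ScoreTable(
        cell_ids=list(cell_ids),
        labels=list(labels),
        scores=scores,
        explained_ratio=basis.explained_ratio,
        loadings=basis.components,
    )


def _centroids(table: ScoreTable, cols) -> dict:
    out = {}
    labels = np.asarray(table.labels)
    for lab in sorted(set(table.labels)):
        out[lab] = table.scores[labels == lab][:, cols].mean(axis=0)
    return out


def score_space_report(
    table: ScoreTable,
    pcs: tuple = (2, 3),
    out_dir=None,
    stem: str = "score_space",
) -> dict:
    """Centroid table + silhouette separation index in a chosen PC plane.

    ``pcs`` are 1-based principal-component indices ((2, 3) inspects the
    classification plane; (1, 2) includes the comprehensive indicator).
    With ``out_dir`` set, writes a scatter PNG and a centroid CSV.  The
    separation index is undefined (NaN) for fewer than two classes.
    """
    for p in pcs:
        if not 1 <= p <= table.scores.shape[1]:
            raise ValueError(f"PC{p} not available (table has {table.scores.shape[1]} PCs)")
    cols = [p - 1 for p in pcs]
    pts = table.scores[:, cols]
    labels = np.asarray(table.labels)
    classes = sorted(set(table.labels))
    centroids = _centroids(table, cols)

    if len(classes) < 2:
        separation = float("nan")
    else:
        from sklearn.metrics import silhouette_score

        separation = float(silhouette_score(pts, labels))

    report = {
        "pcs": tuple(pcs),
        "centroids": {k: v.tolist() for k, v in centroids.items()},
        "separation_index": separation,
        "explained_ratio": table.explained_ratio[cols].tolist(),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [[k, *v] for k, v in centroids.items()],
            columns=["label", f"PC{pcs[0]}", f"PC{pcs[1]}"],
        ).to_csv(out_dir / f"{stem}_centroids.csv", index=False)

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab in classes:
            sel = labels == lab
            ax.scatter(pts[sel, 0], pts[sel, 1], label=lab, s=30)
        for lab, cen in centroids.items():
            ax.scatter(*cen, marker="x", c="k", s=60)
        ax.set_xlabel(f"PC{pcs[0]} score")
        ax.set_ylabel(f"PC{pcs[1]} score")
        ax.legend(frameon=False)
        ax.set_title(f"separation index {separation:.3f}" if np.isfinite(separation) else "single class")
        fig.tight_layout()
        fig.savefig(out_dir / f"{stem}.png", dpi=150)
        plt.close(fig)
        report["plot"] = str(out_dir / f"{stem}.png")
    return report


def nearest_centroid_assign(table: ScoreTable, train_labels=None, pcs=None) -> list:
    """Assign each cell the label of the nearest class centroid (Euclidean).

    Centroids come from ``train_labels`` (default: the table's own labels;
    entries set to None are excluded from centroid estimation).  Ties break
    to the alphabetically first class.  Raises if any class has no labelled
    cell.
    """
    labels = list(table.labels) if train_labels is None else list(train_labels)
    if len(labels) != table.scores.shape[0]:
        raise ValueError("train_labels length must match the number of cells")
    cols = list(range(table.scores.shape[1])) if pcs is None else [p - 1 for p in pcs]
    pts = table.scores[:, cols]
    classes = sorted({lab for lab in labels if lab is not None})
    if not classes:
        raise ValueError("no labelled cells to form centroids")
    cents = []
    for lab in classes:
        sel = np.array([l == lab for l in labels])
        if not sel.any():
            raise ValueError(f"class {lab!r} has no labelled cell")
        cents.append(pts[sel].mean(axis=0))
    cents = np.stack(cents)
    d = np.linalg.norm(pts[:, None, :] - cents[None, :, :], axis=2)
    # argmin returns the first (alphabetically smallest) class on ties
    return [classes[i] for i in np.argmin(d, axis=1)]
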