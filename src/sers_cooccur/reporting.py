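"""Exploratory analysis, annotation and report assembly.

Covers mean-centered PCA of preprocessed spectra, per-condition average
spectra, annotation of wavenumbers with molecular classes from a packaged
band-assignment table, and the assembly of the MAA relation map (long CSV
plus heatmap) that visualizes which spectral variables co-occur with the
SMD-selected important bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _importlib_resources
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .errors import CountError, LabelError, SelectionError
from .forest_smd import RelationMatrix
from .spectra_io import SpectraSet, Spectrum, WavenumberAxis

__all__ = [
    "PcaResult",
    "run_pca",
    "average_spectrum",
    "BandAssignmentTable",
    "load_band_assignments",
    "annotate_band",
    "build_relation_map",
    "plot_relation_heatmap",
    "plot_occurrence_panels",
]

CLASS_COLORS = {"protein": "tab:blue", "lipid": "gold", "dna": "tab:red", "other": "gray"}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """Scores, loadings and explained variance of a mean-centered PCA."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray


def run_pca(sset: SpectraSet, k: int) -> PcaResult:
    """Mean-centered PCA with a deterministic sign convention.

    Each loading is flipped, together with its score column, so that its
    largest-magnitude element is positive; score plots are therefore
    reproducible across runs and platforms.
    """
    if not 1 <= k < sset.n:
        raise CountError(f"need 1 <= k < n, got k={k}, n={sset.n}")
    pca = _SkPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(sset.matrix)
    loadings = pca.components_.copy()
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1.0
            scores[:, c] *= -1.0
    return PcaResult(scores, loadings, pca.explained_variance_.copy())


def average_spectrum(sset: SpectraSet, condition: str) -> Spectrum:
    """Pointwise mean of all spectra carrying the given condition label."""
    mask = sset.labels == condition
    if not mask.any():
        raise LabelError(f"no spectra labelled {condition!r}")
    return Spectrum(sset.axis, sset.matrix[mask].mean(axis=0), {"condition": condition})


# ---------------------------------------------------------------------------
# band assignment
# ---------------------------------------------------------------------------


@dataclass
class BandAssignmentTable:
    """Wavenumber intervals mapped to molecular classes and labels.

    Intervals may overlap; queries are resolved deterministically toward
    the interval whose midpoint is nearest to the queried center.
    """

    rows: pd.DataFrame  # columns lo_cm1, hi_cm1, class_tag, label

    def __post_init__(self) -> None:
        required = {"lo_cm1", "hi_cm1", "class_tag", "label"}
        if not required <= set(self.rows.columns):
            raise LabelError(f"assignment table needs columns {sorted(required)}")
        if (self.rows["lo_cm1"] > self.rows["hi_cm1"]).any():
            raise LabelError("assignment intervals must satisfy lo <= hi")
        if len(self.rows) == 0:
            raise LabelError("empty assignment table")


def load_band_assignments() -> BandAssignmentTable:
    """The packaged assignment table for endolysosomal cell spectra."""
    ref = _importlib_resources.files("sers_cooccur.resources").joinpath(
        "band_assignments.csv"
    )
    with _importlib_resources.as_file(ref) as fp:
        return BandAssignmentTable(pd.read_csv(fp))


def annotate_band(center: float, table: BandAssignmentTable) -> tuple[str, str]:
    """Molecular class and label of the interval containing ``center``.

    Among overlapping intervals the one with the nearest midpoint wins;
    centers outside every interval return ``("other", "unassigned")``.
    """
    rows = table.rows
    hits = rows[(rows["lo_cm1"] <= center) & (center <= rows["hi_cm1"])]
    if len(hits) == 0:
        return "other", "unassigned"
    mid = (hits["lo_cm1"] + hits["hi_cm1"]) / 2.0
    best = hits.loc[(mid - center).abs().idxmin()]
    return str(best["class_tag"]), str(best["label"])


# ---------------------------------------------------------------------------
# relation map
# ---------------------------------------------------------------------------


def build_relation_map(
    rel: RelationMatrix,
    axis: WavenumberAxis,
    table: BandAssignmentTable,
    top_q: float = 0.95,
) -> pd.DataFrame:
    """Long-format relation table of representatives vs. spectral variables.

    Each representative keeps its partners whose MAA lies strictly above the
    ``top_q`` quantile of that representative's row, plus the self entry.
    Columns: representative wavenumber and class, partner wavenumber and
    class, MAA value.
    """
    if not rel.representatives:
        raise SelectionError("relation matrix has no representatives")
    records = []
    centers = axis.centers
    for r, rep in enumerate(rel.representatives):
        row = rel.maa[r]
        cutoff = float(np.quantile(row, top_q))
        rep_class, _ = annotate_band(centers[rep], table)
        for j in range(row.size):
            if j != rep and not row[j] > cutoff:
                continue
            partner_class, _ = annotate_band(centers[j], table)
            records.append(
                {
                    "representative_cm1": centers[rep],
                    "representative_class": rep_class,
                    "partner_cm1": centers[j],
                    "partner_class": partner_class,
                    "maa": row[j],
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "representative_cm1",
            "representative_class",
            "partner_cm1",
            "partner_class",
            "maa",
        ],
    )


def plot_relation_heatmap(
    rel: RelationMatrix,
    axis: WavenumberAxis,
    table: BandAssignmentTable,
    path: str | Path,
    row_order: str = "wavenumber_desc",
) -> Path:
    """Heatmap of MAA rows (representatives, class-colored) vs. variables."""
    order = np.arange(len(rel.representatives))
    if row_order == "wavenumber_desc":
        order = order[np.argsort([-axis.centers[r] for r in rel.representatives])]
    maa = rel.maa[order]
    reps = [rel.representatives[i] for i in order]
    fig, ax = plt.subplots(figsize=(9, max(2.0, 0.35 * len(reps))))
    extent = [axis.centers[0], axis.centers[-1], len(reps), 0]
    im = ax.imshow(maa, aspect="auto", cmap="inferno", vmin=0, vmax=1, extent=extent)
    ax.set_yticks(np.arange(len(reps)) + 0.5)
    labels = []
    for rep in reps:
        cls, _ = annotate_band(axis.centers[rep], table)
        labels.append(f"{axis.centers[rep]:.0f}")
        ax.get_yticklabels()
    ax.set_yticklabels(labels)
    for tick, rep in zip(ax.get_yticklabels(), reps):
        cls, _ = annotate_band(axis.centers[rep], table)
        tick.set_color(CLASS_COLORS.get(cls, "black"))
    ax.set_xlabel("wavenumber / cm$^{-1}$")
    ax.set_ylabel("representative band / cm$^{-1}$")
    fig.colorbar(im, ax=ax, label="mean adjusted agreement")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_occurrence_panels(
    averages: dict,
    histograms: dict,
    path: str | Path,
) -> Path:
    """Paired average-spectrum / occurrence-histogram panels per condition."""
    conditions = list(averages)
    fig, axes = plt.subplots(
        len(conditions), 2, figsize=(10, 2.6 * len(conditions)), squeeze=False
    )
    for r, cond in enumerate(conditions):
        avg = averages[cond]
        hist = histograms[cond]
        axes[r, 0].plot(avg.axis.centers, avg.intensities, lw=0.8)
        axes[r, 0].set_ylabel(f"{cond}\nintensity (norm.)")
        axes[r, 1].bar(hist.grid.centers, hist.relative, width=hist.grid.step * 0.9)
        axes[r, 1].set_ylabel("rel. occurrence")
        axes[r, 1].set_ylim(0, 1)
    for ax in axes[-1]:
        ax.set_xlabel("wavenumber / cm$^{-1}$")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
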