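"""Atlas labels and ROI aggregation.

The analysis is organised around 32 transcallosal white-matter tracts and
their 32 homotopic gray-matter origin/endpoint regions, grouped by lobe
(frontal 17, temporal 3, parietal 6, occipital 6).  Voxelwise metric maps
are averaged within each label, and the per-subject means for the five
metrics (fw, fwcfa, fwcmd, fa, md) across 64 ROIs are assembled into the
subjects x 320-variable analysis table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# ROI abbreviations per lobe.  The white-matter tract set and the
# gray-matter set share names (each tract connects the homotopic pair of
# the named cortical region).
FRONTAL_ROIS = (
    "AOG",       # anterior orbital gyrus
    "GR",        # gyrus rectus
    "IFG_oper",  # inferior frontal gyrus, pars opercularis
    "IFG_orb",   # inferior frontal gyrus, pars orbitalis
    "IFG_tri",   # inferior frontal gyrus, pars triangularis
    "LOG",       # lateral orbital gyrus
    "M1",        # primary motor cortex
    "MedFG",     # medial frontal gyrus
    "mOG",       # medial orbital gyrus
    "mOFG",      # medial orbitofrontal gyrus
    "MFG",       # middle frontal gyrus
    "OC",        # olfactory cortex
    "PMd",       # dorsal premotor cortex
    "PMv",       # ventral premotor cortex
    "preSMA",    # pre-supplementary motor area
    "SMA",       # supplementary motor area
    "SFG",       # superior frontal gyrus
)
TEMPORAL_ROIS = ("ITG", "MTG", "STG")
PARIETAL_ROIS = ("AG", "IPL", "PCL", "S1", "SPL", "SMG")
OCCIPITAL_ROIS = ("CAL", "CUN", "IOG", "LIG", "MOG", "SOG")

ROI_NAMES: tuple[str, ...] = FRONTAL_ROIS + TEMPORAL_ROIS + PARIETAL_ROIS + OCCIPITAL_ROIS
ROI_LOBES: dict[str, str] = {
    **{n: "frontal" for n in FRONTAL_ROIS},
    **{n: "temporal" for n in TEMPORAL_ROIS},
    **{n: "parietal" for n in PARIETAL_ROIS},
    **{n: "occipital" for n in OCCIPITAL_ROIS},
}

# Frontal tracts in which the autism group carries a free-water offset in
# the synthetic cohort (the group-difference structure the cohort
# generator emulates).
FRONTAL_OFFSET_TRACTS = ("GR", "mOG", "OC", "PMd", "PMv", "preSMA", "SMA")

METRICS = ("fw", "fwcfa", "fwcmd", "fa", "md")
TISSUES = ("wm", "gm")
COVARIATE_COLUMNS = ("subject_id", "group", "age_years", "sex")


class GridMismatchError(ValueError):
    """Metric map and label volume live on different grids."""


@dataclass
class LabelAtlas:
    """Integer label volumes for the 32 WM tracts and 32 GM regions.

    Label value ``i + 1`` in each volume maps to ``roi_names[i]``;
    0 is background.
    """

    wm_labels: np.ndarray
    gm_labels: np.ndarray
    roi_names: tuple[str, ...] = ROI_NAMES
    lobes: Mapping[str, str] = field(default_factory=lambda: dict(ROI_LOBES))

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(set(self.roi_names)):
            raise ValueError("duplicate ROI names")
        missing = [n for n in self.roi_names if n not in self.lobes]
        if missing:
            raise ValueError(f"ROIs without a lobe assignment: {missing}")

    def labels(self, tissue: str) -> np.ndarray:
        if tissue == "wm":
            return self.wm_labels
        if tissue == "gm":
            return self.gm_labels
        raise ValueError(f"tissue must be 'wm' or 'gm', got {tissue!r}")

    def sidecar(self) -> dict:
        """JSON-serializable name/lobe mapping for the label volumes."""
        return {
            "labels": {str(i + 1): n for i, n in enumerate(self.roi_names)},
            "lobes": {n: self.lobes[n] for n in self.roi_names},
        }

    @classmethod
    def from_sidecar(cls, wm_labels, gm_labels, sidecar: dict) -> "LabelAtlas":
        items = sorted(sidecar["labels"].items(), key=lambda kv: int(kv[0]))
        names = tuple(name for _, name in items)
        return cls(wm_labels=wm_labels, gm_labels=gm_labels,
                   roi_names=names, lobes=dict(sidecar["lobes"]))

    def save_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=1)


def extract_roi_means(
    metric_map: np.ndarray,
    atlas: LabelAtlas,
    tissue: str,
) -> pd.Series:
    """Mean metric value per ROI label.

    NaN voxels (e.g. CSF-excluded) are ignored; an ROI with no valid
    voxel is reported as missing (NaN), never as zero.  Returns a Series
    indexed by ROI name, with the retained voxel count in ``.attrs``.
    """
    labels = atlas.labels(tissue)
    metric_map = np.asarray(metric_map, dtype=float)
    if metric_map.shape != labels.shape:
        raise GridMismatchError(
            f"metric map shape {metric_map.shape} != label volume shape {labels.shape}"
        )
    means = {}
    counts = {}
    valid = np.isfinite(metric_map)
    for i, name in enumerate(atlas.roi_names):
        sel = (labels == i + 1) & valid
        n = int(sel.sum())
        counts[name] = n
        means[name] = float(metric_map[sel].mean()) if n else np.nan
    out = pd.Series(means, name=f"{tissue}_mean")
    out.attrs["voxel_counts"] = counts
    return out


def metric_columns(
    metrics: Iterable[str] = METRICS,
    tissues: Iterable[str] = TISSUES,
    roi_names: Iterable[str] = ROI_NAMES,
) -> list[str]:
    """Canonical column order: metric, then tissue, then ROI name."""
    return [f"{m}_{t}_{r}" for m in metrics for t in tissues for r in roi_names]


def parse_variable(column: str) -> tuple[str, str, str]:
    """Split '{metric}_{tissue}_{roi}' into its parts."""
    metric, tissue, roi = column.split("_", 2)
    if metric not in METRICS or tissue not in TISSUES:
        raise ValueError(f"not a metric column: {column!r}")
    return metric, tissue, roi


def variable_family(column: str) -> str:
    """FDR family id (metric x tissue) of a metric column."""
    metric, tissue, _ = parse_variable(column)
    return f"{metric}_{tissue}"


def assemble_variable_table(subject_rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-subject ROI means into the analysis table.

    Each row dict carries ``subject_id``, ``group``, ``age_years``,
    ``sex``, optional extra covariates, and metric values keyed
    '{metric}_{tissue}_{roi}'.  Rows are sorted by subject id and metric
    columns by the canonical (metric, tissue, ROI) order, so the output
    is independent of input ordering.  A subject missing a metric keeps
    its row with missing cells.
    """
    rows = list(subject_rows)
    if not rows:
        raise ValueError("no subjects")
    df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject ids: {dupes}")
    metric_cols = [c for c in metric_columns() if c in df.columns]
    extra = [
        c for c in df.columns
        if c not in metric_cols and c not in COVARIATE_COLUMNS
    ]
    cols = list(COVARIATE_COLUMNS) + sorted(extra) + metric_cols
    df = df.reindex(columns=cols)
    return df.sort_values("subject_id", kind="stable").reset_index(drop=True)
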