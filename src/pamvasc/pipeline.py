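"""End-to-end orchestration: RF volumes / MIPs -> features -> classification.

`run_extract` turns a batch of inputs (RF HDF5 containers and/or MIP TIFFs)
into a per-image feature table: the RF branch contributes the spectral mean
frequency, the structural branch contributes morphometric and topological
features of the segmented vasculature.  `run_full` takes a labelled feature
table through screening, selection, the cosine-similarity network, the 2D
embedding with its in-sample boundary, and the LOOCV classifier, writing a
JSON report, CSV artifacts and publication-style figures.

Images whose vessel mask comes out empty are excluded and listed in the run
log rather than imputed, mirroring a quality-control exclusion workflow.
Every run directory gets a manifest carrying the configuration hash so
outputs are traceable to their exact parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    feature_selection,
    morphometry,
    network_topology,
    rf_preprocessing,
    similarity_classifier,
    spectral_analysis,
    vessel_segmentation,
)
from .rf_preprocessing import MIPImage, ValidationError

logger = logging.getLogger("pamvasc")

__all__ = ["RunConfig", "run_extract", "run_full", "extract_image_features"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one place; hashable for provenance."""

    band_low_hz: float = rf_preprocessing.DEFAULT_BAND_LOW_HZ
    band_high_hz: float = rf_preprocessing.DEFAULT_BAND_HIGH_HZ
    dynamic_range_db: float = rf_preprocessing.DEFAULT_DYNAMIC_RANGE_DB
    pixel_size_um: float = rf_preprocessing.DEFAULT_PIXEL_SIZE_UM
    clahe_clip: float = vessel_segmentation.DEFAULT_CLAHE_CLIP
    ball_radius_px: int = vessel_segmentation.DEFAULT_BALL_RADIUS_PX
    enhance: bool = True
    binarize_method: str = "otsu"
    min_object_area_px: int = vessel_segmentation.DEFAULT_MIN_OBJECT_AREA_PX
    spectral_window_px: int = spectral_analysis.DEFAULT_WINDOW_PX
    noise_floor_quantile: float = spectral_analysis.DEFAULT_NOISE_FLOOR_QUANTILE
    k_features: int = feature_selection.DEFAULT_K
    corr_threshold: float = feature_selection.DEFAULT_CORR_THRESHOLD
    seed: int = 42
    layout_iterations: int = 500

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.dynamic_range_db <= 0:
            raise ValidationError("physical parameters must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValidationError("band edges must satisfy 0 < low < high")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _structural_features(
    mip: MIPImage, config: RunConfig
) -> dict[str, float]:
    """Morphometry + topology from one MIP image."""
    img = mip
    if config.enhance:
        img = vessel_segmentation.enhance_and_subtract(
            img, clahe_clip=config.clahe_clip, ball_radius_px=config.ball_radius_px
        )
    mask = vessel_segmentation.binarize(
        img, method=config.binarize_method, min_object_area_px=config.min_object_area_px
    )
    if not mask.mask.any():
        raise ValidationError("empty vessel mask")
    skel = vessel_segmentation.skeletonize(mask)
    area = network_topology.roi_area(mask.mask.shape, mask.pixel_size_um)
    dmap = morphometry.diameter_map(mask, skel)
    morpho = morphometry.morphometric_features(dmap, mask, skel, area)
    graph = network_topology.build_skeleton_graph(skel)
    topo = network_topology.topology_features(graph, area)
    return {**morpho.as_dict(), **topo.as_dict()}


def extract_image_features(
    config: RunConfig,
    rf: rf_preprocessing.RFVolume | None = None,
    mip: MIPImage | None = None,
) -> dict[str, float]:
    """Feature row for one image, from its RF volume and/or its MIP.

    When only the RF volume is given, the MIP is derived from it; the
    spectral mean frequency always comes from the (bandpassed) RF data and is
    reported in MHz.
    """
    if rf is None and mip is None:
        raise ValidationError("need an RF volume or a MIP image")
    row: dict[str, float] = {}
    if rf is not None:
        filtered = rf_preprocessing.bandpass_filter(
            rf, config.band_low_hz, config.band_high_hz
        )
        mf = spectral_analysis.mean_frequency_of_volume(
            filtered, config.spectral_window_px, config.noise_floor_quantile
        )
        row["mean_frequency_mhz"] = mf.mean_freq_hz / 1e6
        if mip is None:
            env = rf_preprocessing.hilbert_envelope(filtered)
            mip = rf_preprocessing.max_intensity_projection(env, rf.pixel_size_um)
    assert mip is not None
    try:
        row.update(_structural_features(mip, config))
    except ValidationError:
        if not row:  # no RF branch either: nothing at all to report
            raise
        logger.warning(
            "structural analysis failed; keeping spectral features only",
            exc_info=True,
        )
    return row


def run_extract(
    config: RunConfig,
    inputs: list[str | Path],
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """One feature row per input file (RF ``.h5`` or MIP ``.tif``/``.png``).

    Unreadable or unprocessable inputs are logged and skipped; the run
    continues and the failures are summarized at the end.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    if not inputs:
        warnings.warn("empty input list: returning an empty feature table", stacklevel=2)
    for path in inputs:
        path = Path(path)
        t0 = time.perf_counter()
        try:
            if path.suffix.lower() in {".h5", ".hdf5"}:
                rf = rf_preprocessing.read_rf_h5(path)
                row = extract_image_features(config, rf=rf)
            else:
                mip = rf_preprocessing.read_mip_tiff(path)
                row = extract_image_features(config, mip=mip)
            row["image"] = path.stem
            rows.append(row)
            logger.info("extracted %s in %.2fs", path.name, time.perf_counter() - t0)
        except Exception as exc:  # per-file isolation: one bad scan never kills the run
            failures.append((str(path), str(exc)))
            logger.error("failed on %s: %s", path, exc)
    if failures:
        logger.warning("%d of %d inputs failed: %s", len(failures), len(inputs), failures)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("image")
    if out_csv is not None:
        df.to_csv(out_csv)
    return df


def run_full(
    config: RunConfig,
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    label_column: str = feature_selection.LABEL_COLUMN,
    make_figures: bool = True,
    feature_names: list[str] | None = None,
) -> dict:
    """Selection -> similarity network -> embedding + boundary -> LOOCV report.

    ``feature_names`` fixes the feature set up front and bypasses the
    screening/pruning stage — useful when the discriminative set is already
    established (Welch statistics are still reported for those features).
    When extreme class separation makes every informative feature correlate
    through the class difference, automatic pruning legitimately collapses
    to a single feature; a fixed set is the right tool there.
    """
    if label_column not in table.columns:
        raise ValidationError(f"feature table has no {label_column!r} column")

    if feature_names is not None:
        missing = [f for f in feature_names if f not in table.columns]
        if missing:
            raise ValidationError(f"feature table lacks columns: {missing}")
        selection = feature_selection.select_features(
            table[list(feature_names) + [label_column]],
            k=len(feature_names), corr_threshold=1.0, alpha=1.0,
            label_column=label_column,
        )
        selected = list(feature_names)
    else:
        selection = feature_selection.select_features(
            table, k=config.k_features, corr_threshold=config.corr_threshold,
            label_column=label_column,
        )
        selected = selection.selected
    if len(selected) < 2:
        raise ValidationError(
            "fewer than 2 features selected; nothing to classify on"
        )
    sim = similarity_classifier.cosine_similarity(
        table, selected, label_column=label_column
    )
    emb = similarity_classifier.force_layout(
        sim, seed=config.seed, n_iter=config.layout_iterations
    )
    boundary = similarity_classifier.boundary_2d(emb, sim.labels)
    cv = similarity_classifier.loocv(sim)

    report = {
        "config_hash": config.config_hash(),
        "selected_features": selected,
        "n_samples": len(sim),
        "auc": cv.auc,
        "sensitivity": cv.confusion["sensitivity"],
        "specificity": cv.confusion["specificity"],
        "accuracy": cv.confusion["accuracy"],
        "confusion": {k: cv.confusion[k] for k in ("tp", "fn", "tn", "fp")},
        "embedding_n_correct_side": boundary.n_correct_side,
        "per_sample_probabilities": {
            sid: float(p) for sid, p in zip(sim.ids, cv.probabilities)
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids).to_csv(
            out_dir / "similarity_matrix.csv"
        )
        pd.DataFrame(
            {"id": sim.ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1], "label": sim.labels}
        ).to_csv(out_dir / "embedding.csv", index=False)
        similarity_classifier.roc_curve_points(cv.probabilities, cv.labels).to_csv(
            out_dir / "roc_points.csv", index=False
        )
        (out_dir / "selection.json").write_text(
            json.dumps(selection.to_json_dict(), indent=2)
        )
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        (out_dir / "run_manifest.json").write_text(
            json.dumps(
                {"config": dataclasses.asdict(config), "config_hash": config.config_hash()},
                indent=2,
            )
        )
        if make_figures:
            _make_figures(out_dir, table, selection, sim, emb, boundary, cv, label_column)
    return report


def _make_figures(out_dir, table, selection, sim, emb, boundary, cv, label_column):
    """Boxplots of selected features, embedding + boundary, ROC + confusion."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [
        table[table[label_column] == lab] for lab in ("normal_benign", "ec_ein")
    ]
    selected = list(selection.stats.index)
    fig, axes = plt.subplots(1, len(selected), figsize=(3 * len(selected), 3.2))
    for ax, feat in zip(np.atleast_1d(axes), selected):
        ax.boxplot(
            [g[feat].dropna() for g in groups], tick_labels=["normal/benign", "EC/EIN"]
        )
        p = selection.stats.loc[feat, "p"]
        ax.set_title(f"{feat}\np={p:.2e}", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "feature_boxplots.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"normal_benign": "tab:blue", "ec_ein": "tab:red"}
    for lab in colors:
        pts = emb.coords[sim.labels == lab]
        ax.scatter(pts[:, 0], pts[:, 1], c=colors[lab], label=lab, s=30)
    a, b = boundary.coef
    if abs(b) > 1e-12:
        xs = np.linspace(emb.coords[:, 0].min(), emb.coords[:, 0].max(), 50)
        ax.plot(xs, -(a * xs + boundary.intercept) / b, "g--", label="boundary")
    ax.legend(fontsize=8)
    ax.set_title("cosine-similarity network embedding")
    fig.tight_layout()
    fig.savefig(out_dir / "embedding_boundary.png", dpi=150)
    plt.close(fig)

    roc = similarity_classifier.roc_curve_points(cv.probabilities, cv.labels)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc["fpr"], roc["tpr"], "-o", ms=3)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"LOOCV ROC (AUC = {cv.auc:.3f})")
    fig.tight_layout()
    fig.savefig(out_dir / "roc.png", dpi=150)
    plt.close(fig)
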