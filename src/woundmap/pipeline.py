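"""End-to-end orchestration: movie → masks → fields → maps → descriptors.

``run_experiment`` executes every stage on one movie and returns (and
optionally writes) all intermediate products plus a manifest sufficient to
re-run the analysis bit-identically.  ``run_cohort`` runs a set of labeled
movies and aggregates their descriptors into leave-one-out classification,
rank-sum significance and PCA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

import woundmap
from woundmap.classify import (
    ClassificationResult,
    DescriptorVector,
    exact_ranksum,
    loocv_svm,
    normalize,
    pca2,
    velocity_descriptor,
)
from woundmap.config import RunConfig
from woundmap.motion import estimate_movie_fields, toward_wound_components
from woundmap.movies import MovieStack, write_matrix
from woundmap.segmentation import segment_movie, wound_masks
from woundmap.strips import (
    DistanceMap,
    PhasePartition,
    VelocityMagnitudeMap,
    build_velocity_map,
    detect_phases,
    movie_distance_maps,
)
from woundmap.texture import lbp_histogram_series, phase_texture_descriptor

__all__ = ["ExperimentResult", "run_experiment", "CohortReport", "run_cohort",
           "render_map_png"]


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


@dataclass
class ExperimentResult:
    """All products of one pipeline run."""

    movie_name: str
    config: RunConfig
    cellular_masks: np.ndarray
    wound_mask_stack: np.ndarray
    phases: PhasePartition
    distance_maps: list[DistanceMap]
    fields: list
    velocity_map: VelocityMagnitudeMap
    lbp_series: np.ndarray
    velocity_vector: Optional[DescriptorVector]
    texture_vector: Optional[np.ndarray]
    manifest: dict = field(default_factory=dict)


def run_experiment(
    movie: MovieStack,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    phases: PhasePartition | None = None,
    condition: str = "",
) -> ExperimentResult:
    """Run the full analysis pipeline on one movie.

    Healing phases are detected automatically unless supplied (the analysis
    is defined relative to two time points — first contact and full closure
    — which an operator may also fix by hand).  Descriptor vectors are
    computed when the required phase boundaries exist; otherwise they are
    left as None with the reason recorded in the manifest.
    """
    config = config or RunConfig()
    stage = "segmentation"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        cellular = segment_movie(movie, config)
        timings[stage] = time.perf_counter() - t0

        stage = "wound tracking"
        t0 = time.perf_counter()
        patch_px = config.patch_size_px(movie.pixel_size_um)
        wounds = wound_masks(cellular, min_area_px=patch_px * patch_px)
        if phases is None:
            phases = detect_phases(wounds, config.closure_area_fraction, cellular)
        dmaps = movie_distance_maps(cellular, wounds, movie.pixel_size_um)
        timings[stage] = time.perf_counter() - t0

        stage = "motion estimation"
        t0 = time.perf_counter()
        fields = estimate_movie_fields(movie, cellular, config)
        fields = [
            toward_wound_components(f, d.dist_um, movie.pixel_size_um)
            for f, d in zip(fields, dmaps[:-1])
        ]
        timings[stage] = time.perf_counter() - t0

        stage = "velocity map"
        t0 = time.perf_counter()
        vmap = build_velocity_map(
            fields, dmaps[:-1], config.strip_width(), config.max_distance_um,
            movie.frame_interval_min,
        )
        timings[stage] = time.perf_counter() - t0

        stage = "texture"
        t0 = time.perf_counter()
        lbp = lbp_histogram_series(movie, cellular)
        timings[stage] = time.perf_counter() - t0

        stage = "descriptors"
        velocity_vec: Optional[DescriptorVector] = None
        texture_vec: Optional[np.ndarray] = None
        skip_reason = None
        try:
            velocity_vec = velocity_descriptor(
                vmap, phases, config.n_distance_intervals, config.phases_used,
                config.max_distance_um, experiment=movie.name, condition=condition,
            )
        except ValueError as exc:
            skip_reason = str(exc)
        if phases.t_contact is not None and phases.t_closure is not None \
                and phases.t_closure > phases.t_contact:
            texture_vec = phase_texture_descriptor(lbp, phases, phase=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "movie": movie.name,
        "movie_sha256": _sha256(movie.frames),
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_min": movie.frame_interval_min,
        "n_frames": movie.n_frames,
        "config": dataclasses.asdict(config),
        "phases": {"t_contact": phases.t_contact, "t_closure": phases.t_closure},
        "velocity_map_sha256": _sha256(np.nan_to_num(vmap.M)),
        "lbp_sha256": _sha256(np.nan_to_num(lbp)),
        "velocity_descriptor_skipped": skip_reason,
        "version": woundmap.__version__,
        "stage_seconds": timings,
        "outputs": {},
    }
    result = ExperimentResult(
        movie.name, config, cellular, wounds, phases, dmaps, fields, vmap, lbp,
        velocity_vec, texture_vec, manifest,
    )
    if out_dir is not None:
        _write_outputs(result, movie, Path(out_dir))
    return result


def _write_outputs(result: ExperimentResult, movie: MovieStack, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = result.manifest["outputs"]

    vmap = result.velocity_map
    map_df = pd.DataFrame(
        vmap.M,
        index=[f"t{t}" for t in range(vmap.n_frames)],
        columns=[f"{c:.1f}um" for c in vmap.bin_centers_um()],
    )
    map_path = out_dir / "velocity_map.csv"
    map_df.to_csv(map_path)  # NaN cells stay empty: missing, not zero
    outputs["velocity_map"] = str(map_path)

    lbp_path = out_dir / "lbp_histograms.csv"
    pd.DataFrame(result.lbp_series, columns=[f"code{k}" for k in range(10)]).to_csv(lbp_path)
    outputs["lbp_histograms"] = str(lbp_path)

    areas = result.wound_mask_stack.reshape(movie.n_frames, -1).sum(axis=1)
    area_path = out_dir / "wound_area.csv"
    pd.DataFrame({
        "frame": np.arange(movie.n_frames),
        "wound_area_um2": areas * movie.pixel_size_um**2,
    }).to_csv(area_path, index=False)
    outputs["wound_area"] = str(area_path)

    if result.velocity_vector is not None:
        desc_path = out_dir / "velocity_descriptor.csv"
        write_matrix(result.velocity_vector.values[None, :], desc_path,
                     row_labels=[movie.name])
        outputs["velocity_descriptor"] = str(desc_path)

    png_path = out_dir / "velocity_map.png"
    render_map_png(vmap, result.phases, png_path)
    outputs["velocity_map_png"] = str(png_path)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def render_map_png(vmap: VelocityMagnitudeMap, phases: PhasePartition,
                   path: str | Path) -> None:
    """Render the velocity magnitude map as a heatmap with phase lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    times_hr = np.arange(vmap.n_frames) * vmap.frame_interval_min / 60.0
    extent = (0, times_hr[-1] if len(times_hr) > 1 else 1.0,
              vmap.n_bins * vmap.strip_width_um, 0)
    im = ax.imshow(vmap.M.T, aspect="auto", extent=extent, cmap="jet",
                   interpolation="nearest")
    for t_frame in (phases.t_contact, phases.t_closure):
        if t_frame is not None:
            ax.axvline(t_frame * vmap.frame_interval_min / 60.0, color="k", lw=1.5)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("distance from wound (µm)")
    fig.colorbar(im, ax=ax, label="speed (µm/h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class CohortReport:
    """Aggregated classification report over a labeled cohort."""

    descriptors: pd.DataFrame
    loocv_raw: ClassificationResult
    loocv_normalized: ClassificationResult
    ranksum_p_raw: float
    ranksum_p_normalized: float
    pca_coords: np.ndarray
    pca_explained: np.ndarray
    experiments: list[str]
    labels: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "experiments": self.experiments,
            "labels": self.labels,
            "accuracy_raw": self.loocv_raw.accuracy,
            "accuracy_normalized": self.loocv_normalized.accuracy,
            "ranksum_p_raw": self.ranksum_p_raw,
            "ranksum_p_normalized": self.ranksum_p_normalized,
            "pca_explained": self.pca_explained.tolist(),
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_cohort(
    movies: Sequence[MovieStack],
    labels: Sequence[str],
    config: RunConfig | None = None,
    phases_list: Sequence[PhasePartition | None] | None = None,
    out_dir: str | Path | None = None,
) -> CohortReport:
    """Analyze a labeled cohort of movies and classify the treatment.

    Every movie runs through the full pipeline; the per-experiment velocity
    descriptors are classified raw and norm-1 normalized with leave-one-out
    linear SVM, scored with the exact rank-sum test, and projected with
    2-component PCA.
    """
    config = config or RunConfig()
    labels = list(labels)
    if len(movies) != len(labels):
        raise ValueError("one label per movie required")
    unique, counts = np.unique(labels, return_counts=True)
    if unique.size < 2 or counts.min() < 2:
        raise ValueError(
            "leave-one-out classification needs at least two movies in each "
            f"of at least two classes; got {dict(zip(unique, counts))}"
        )
    if phases_list is None:
        phases_list = [None] * len(movies)

    vectors = []
    names = []
    for movie, label, ph in zip(movies, labels, phases_list):
        res = run_experiment(
            movie, config,
            out_dir=None if out_dir is None else Path(out_dir) / movie.name,
            phases=ph, condition=label,
        )
        if res.velocity_vector is None:
            raise ValueError(
                f"{movie.name}: velocity descriptor unavailable "
                f"({res.manifest['velocity_descriptor_skipped']})"
            )
        vectors.append(res.velocity_vector.values)
        names.append(movie.name)
    lengths = {v.size for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent descriptor lengths across movies: {sorted(lengths)}")

    X = np.asarray(vectors)
    Xn = np.asarray([normalize(v) for v in vectors])
    loocv_raw = loocv_svm(X, labels, C=config.svm_c, standardize=config.svm_standardize)
    loocv_norm = loocv_svm(Xn, labels, C=config.svm_c, standardize=config.svm_standardize)
    coords, explained = pca2(Xn)

    desc = pd.DataFrame(X, index=names)
    desc.insert(0, "label", labels)
    report = CohortReport(
        descriptors=desc,
        loocv_raw=loocv_raw,
        loocv_normalized=loocv_norm,
        ranksum_p_raw=loocv_raw.ranksum_p,
        ranksum_p_normalized=loocv_norm.ranksum_p,
        pca_coords=coords,
        pca_explained=explained,
        experiments=names,
        labels=labels,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        desc.to_csv(out_dir / "descriptors.csv")
        report.to_json(out_dir / "cohort_report.json")
    return report
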