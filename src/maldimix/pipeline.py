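"""End-to-end calibration workflow shared by the CLI and the test/analysis
entry points.

The five-step protocol: (1) define two-component calibration mixtures,
(2) record (here: load or simulate) spectra of pures and mixtures,
(3) preprocess and reduce to informative peaks, (4) fit and LOO-validate
the PLS and ANN calibrators, (5) predict contamination in unknown samples
with the trained bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from .errors import ParameterError, ValidationError
from .evaluate import CalibrationResult
from .io import SampleManifest, Spectrum, read_manifest, read_spectrum
from .pca import PCAResult, pca_decompose
from .preprocess import (
    IntensityMatrix,
    MzGrid,
    align_set,
    align_to_reference,
    build_matrix,
    normalize,
    resample,
    smooth,
    subtract_baseline,
    threshold_filter,
)
from .select import PeakPanel, combine_panels, lasso_select, sd_ranking, spls_select


@dataclass
class PipelineConfig:
    """All tunables of the calibration pipeline, validated up front."""

    # m/z grid
    grid_lo: float = 2000.0
    grid_hi: float = 20000.0
    grid_bins: int = 30000
    # preprocessing
    max_shift_bins: int = 50
    baseline_half_window: int = 250
    smooth_window: int = 21
    smooth_polyorder: int = 3
    norm_mode: str = "l1"
    threshold: float = 1e-3
    # peak panel
    panel_size: int = 10
    panel_min_spacing_da: float = 15.0
    lasso_n_lambda: int = 100
    lasso_cv_folds: int = 5
    spls_components: int = 2
    spls_sparsity: float = 0.8
    # calibrators
    pls_components: int = 10
    ann_hidden: int = 4
    ann_epochs: int = 2000
    ann_learning_rate: float = 0.01
    ann_momentum: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        """Check every parameter before any I/O; collect all violations."""
        problems = []
        if not self.grid_lo < self.grid_hi:
            problems.append("grid_lo must be < grid_hi")
        if self.grid_bins < 2:
            problems.append("grid_bins must be >= 2")
        if self.max_shift_bins < 0 or self.max_shift_bins >= self.grid_bins:
            problems.append("max_shift_bins must be in [0, grid_bins)")
        if self.baseline_half_window < 1:
            problems.append("baseline_half_window must be >= 1")
        if self.smooth_window % 2 == 0 or self.smooth_window < 3:
            problems.append("smooth_window must be odd and >= 3")
        if self.smooth_polyorder >= self.smooth_window:
            problems.append("smooth_polyorder must be < smooth_window")
        if self.norm_mode not in ("l1", "l2"):
            problems.append("norm_mode must be 'l1' or 'l2'")
        if self.threshold < 0:
            problems.append("threshold must be >= 0")
        if self.panel_size < 1:
            problems.append("panel_size must be >= 1")
        if self.panel_min_spacing_da < 0:
            problems.append("panel_min_spacing_da must be >= 0")
        if self.lasso_cv_folds < 2:
            problems.append("lasso_cv_folds must be >= 2")
        if not 0 <= self.spls_sparsity < 1:
            problems.append("spls_sparsity must be in [0, 1)")
        if self.spls_components < 1:
            problems.append("spls_components must be >= 1")
        if self.pls_components < 1:
            problems.append("pls_components must be >= 1")
        if self.ann_hidden < 1 or self.ann_epochs < 1:
            problems.append("ann_hidden and ann_epochs must be >= 1")
        if self.ann_learning_rate <= 0:
            problems.append("ann_learning_rate must be > 0")
        if not 0 <= self.ann_momentum < 1:
            problems.append("ann_momentum must be in [0, 1)")
        if problems:
            raise ParameterError("invalid configuration: " + "; ".join(problems))

    @property
    def grid(self) -> MzGrid:
        return MzGrid(self.grid_lo, self.grid_hi, self.grid_bins)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known - {"generator"}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def load_spectra(manifest: SampleManifest, base_dir: str | Path) -> list[Spectrum]:
    """Read every spectrum referenced by the manifest (paths relative to
    ``base_dir``)."""
    base = Path(base_dir)
    out = []
    for _, row in manifest.table.iterrows():
        p = Path(row["file"])
        if not p.is_absolute():
            p = base / p
        out.append(read_spectrum(p, sample_id=row["sample_id"],
                                 replicate=int(row["replicate"])))
    return out


@dataclass
class PreprocessResult:
    matrix: IntensityMatrix          # thresholded fingerprint matrix
    full_matrix: IntensityMatrix     # normalized matrix on the full grid
    offsets: np.ndarray              # alignment offsets per spectrum
    reference: np.ndarray            # aligned median reference (full grid)
    grid_indices: np.ndarray         # grid bin index of each kept column


def preprocess_dataset(
    spectra: list[Spectrum], manifest: SampleManifest, cfg: PipelineConfig
) -> PreprocessResult:
    """Run chain (i)-(v) plus the intensity-threshold filter."""
    grid = cfg.grid
    resampled = [resample(s, grid) for s in spectra]
    aligned, offsets = align_set(resampled, cfg.max_shift_bins)
    reference = np.median(np.stack([s.intensity for s in aligned]), axis=0)
    normalized = []
    for s in aligned:
        s = subtract_baseline(s, cfg.baseline_half_window)
        s = smooth(s, cfg.smooth_window, cfg.smooth_polyorder)
        normalized.append(normalize(s, cfg.norm_mode))
    full = build_matrix(normalized, manifest)
    reduced = threshold_filter(full, cfg.threshold)
    step = grid.step
    grid_indices = np.rint((reduced.col_mz - grid.lo) / step).astype(int)
    return PreprocessResult(reduced, full, offsets, reference, grid_indices)


def select_panel(
    matrix: IntensityMatrix, y: np.ndarray, cfg: PipelineConfig
) -> tuple[PeakPanel, IntensityMatrix]:
    """Informative-peak selection by the three methods, merged to the
    configured panel size; returns the panel and the reduced matrix."""
    scores = sd_ranking(matrix)
    lasso_idx = lasso_select(matrix, y, n_lambda=cfg.lasso_n_lambda,
                             cv_folds=cfg.lasso_cv_folds, seed=cfg.seed)
    spls_idx = spls_select(matrix, y, n_components=cfg.spls_components,
                           sparsity=cfg.spls_sparsity, seed=cfg.seed)
    panel = combine_panels(scores, lasso_idx, spls_idx, cfg.panel_size,
                           min_spacing_da=cfg.panel_min_spacing_da)
    selected = matrix.select_columns(panel.indices, stage="selected")
    return panel, selected


@dataclass
class CalibrationBundle:
    """Everything needed to predict new samples: config snapshot, aligned
    reference spectrum, panel grid indices, and the trained models."""

    config: PipelineConfig
    reference: np.ndarray
    panel_grid_indices: np.ndarray
    panel_mz: np.ndarray
    ann: cal.ANNModel
    pls: cal.PLSModel
    total: int | None = None

    def save(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "reference": self.reference.tolist(),
            "panel_grid_indices": self.panel_grid_indices.tolist(),
            "panel_mz": self.panel_mz.tolist(),
            "ann": self.ann.to_json(),
            "pls": {
                "n_components": self.pls.n_components,
                "coef": self.pls.coef.tolist(),
                "intercept": self.pls.intercept,
                "x_mean": self.pls.x_mean.tolist(),
                "y_mean": self.pls.y_mean,
                "W": self.pls.W.tolist(),
                "P": self.pls.P.tolist(),
                "q": self.pls.q.tolist(),
            },
            "total": self.total,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationBundle":
        d = json.loads(Path(path).read_text())
        p = d["pls"]
        return cls(
            config=PipelineConfig(**d["config"]),
            reference=np.asarray(d["reference"], float),
            panel_grid_indices=np.asarray(d["panel_grid_indices"], int),
            panel_mz=np.asarray(d["panel_mz"], float),
            ann=cal.ANNModel.from_json(d["ann"]),
            pls=cal.PLSModel(
                n_components=p["n_components"],
                coef=np.asarray(p["coef"], float),
                intercept=p["intercept"],
                x_mean=np.asarray(p["x_mean"], float),
                y_mean=p["y_mean"],
                W=np.asarray(p["W"], float),
                P=np.asarray(p["P"], float),
                q=np.asarray(p["q"], float),
            ),
            total=d.get("total"),
        )


@dataclass
class CalibrationRun:
    """Output of the full calibration workflow on one dataset."""

    panel: PeakPanel
    matrix: IntensityMatrix          # stage 'selected'
    loo_pls: CalibrationResult
    loo_ann: CalibrationResult
    bundle: CalibrationBundle
    preprocess: PreprocessResult

    def summary(self) -> dict:
        """Benchmark-table-shaped summary: RMS, k, R^2 per calibrator."""
        return {
            "PLS": {"RMS": self.loo_pls.rms, "k": self.loo_pls.k,
                    "R2": self.loo_pls.r2},
            "ANN": {"RMS": self.loo_ann.rms, "k": self.loo_ann.k,
                    "R2": self.loo_ann.r2},
        }


def run_calibration(
    spectra: list[Spectrum],
    manifest: SampleManifest,
    cfg: PipelineConfig,
    group_loo: bool = False,
) -> CalibrationRun:
    """Preprocess, select peaks, LOO-validate PLS and ANN, and fit the
    final models on all rows.

    Each technical replicate is one row; ``group_loo=True`` leaves out all
    replicates of a mixture together instead of single spectra.
    """
    cfg.validate()
    prep = preprocess_dataset(spectra, manifest, cfg)
    y = manifest.y_contaminant
    panel, selected = select_panel(prep.matrix, y, cfg)
    groups = list(manifest.table["sample_id"]) if group_loo else None
    pls_trainer = cal.make_pls_trainer(cfg.pls_components)
    ann_trainer = cal.make_ann_trainer(
        n_hidden=cfg.ann_hidden, epochs=cfg.ann_epochs,
        learning_rate=cfg.ann_learning_rate, momentum=cfg.ann_momentum,
    )
    loo_pls = cal.loo_cross_validate(pls_trainer, selected, y,
                                     row_ids=selected.row_ids, seed=cfg.seed,
                                     groups=groups, label="PLS")
    loo_ann = cal.loo_cross_validate(ann_trainer, selected, y,
                                     row_ids=selected.row_ids, seed=cfg.seed,
                                     groups=groups, label="ANN")
    # final models on the full dataset
    ncomp = min(cfg.pls_components, selected.shape[0] - 1, selected.shape[1])
    pls_model = cal.pls_fit(selected, y, ncomp)
    ann_model = cal.ann_init(selected.shape[1], cfg.ann_hidden, seed=cfg.seed)
    ann_model, _ = cal.ann_train(ann_model, selected, y, epochs=cfg.ann_epochs,
                                 learning_rate=cfg.ann_learning_rate,
                                 momentum=cfg.ann_momentum)
    totals = manifest.table["n_cells_A"] + manifest.table["n_cells_B"]
    total = int(totals.iloc[0]) if totals.nunique() == 1 else None
    bundle = CalibrationBundle(
        config=cfg, reference=prep.reference,
        panel_grid_indices=prep.grid_indices[panel.indices],
        panel_mz=panel.mz.copy(), ann=ann_model, pls=pls_model, total=total,
    )
    return CalibrationRun(panel=panel, matrix=selected, loo_pls=loo_pls,
                          loo_ann=loo_ann, bundle=bundle, preprocess=prep)


def preprocess_single(spectrum: Spectrum, bundle: CalibrationBundle) -> np.ndarray:
    """Preprocess one new spectrum on the calibrated grid and return its
    panel intensity vector."""
    cfg = bundle.config
    uncovered = bundle.panel_mz[
        (bundle.panel_mz < spectrum.mz[0]) | (bundle.panel_mz > spectrum.mz[-1])
    ]
    if uncovered.size:
        raise ValidationError(
            f"spectrum {spectrum.sample_id!r} does not cover panel m/z "
            f"{uncovered[0]:.1f} (input range {spectrum.mz[0]:.1f}-"
            f"{spectrum.mz[-1]:.1f})"
        )
    s = resample(spectrum, cfg.grid)
    s, _ = align_to_reference(s, bundle.reference, cfg.max_shift_bins)
    s = subtract_baseline(s, cfg.baseline_half_window)
    s = smooth(s, cfg.smooth_window, cfg.smooth_polyorder)
    s = normalize(s, cfg.norm_mode)
    return s.intensity[bundle.panel_grid_indices]


def predict_samples(
    bundle: CalibrationBundle, spectra: list[Spectrum], model: str = "ann"
) -> pd.DataFrame:
    """Predict contaminant cell counts (and percent of total, when the
    training design total is known) for new spectra."""
    if model not in ("ann", "pls"):
        raise ParameterError("model must be 'ann' or 'pls'")
    X = np.stack([preprocess_single(s, bundle) for s in spectra])
    pred = (cal.ann_predict(bundle.ann, X) if model == "ann"
            else cal.pls_predict(bundle.pls, X))
    out = pd.DataFrame({
        "sample_id": [s.sample_id for s in spectra],
        "replicate": [s.replicate for s in spectra],
        "predicted_n_cells_B": pred,
    })
    if bundle.total:
        out["predicted_percent_B"] = 100.0 * pred / bundle.total
    return out


def pca_diagnostics(matrix: IntensityMatrix, n_components: int = 10) -> PCAResult:
    """PCA on the thresholded fingerprint matrix (discrimination / scree)."""
    n_components = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    return pca_decompose(matrix, n_components)
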