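"""Synthetic two-component intact-cell MALDI-like calibration datasets.

Two cell-type profiles (host A, contaminant B) share most peak locations
but each carries a few unique marker peaks.  A mixture spectrum is rendered
from the design (n_cells_A, n_cells_B) by

1. per-peak linear combination of the per-cell profiles,
2. a saturating intensity response with cross-component ionization
   suppression (the "MALDI effects": peak intensity is not proportional to
   analyte load except in a narrow range),
3. Gaussian peak shapes on an irregular raw m/z axis,
4. an exponentially decaying chemical baseline, a global m/z jitter per
   replicate, multiplicative per-peak noise and additive noise.

Setting gamma = 1 switches the saturation off (identity response) and
together with suppression = 0 and zero noise yields an exactly linear
mixing model — the closed-form limit used to validate the calibrators.
Component profiles are scaled to equal total ion yield per cell so that in
this limit the sum-normalized fingerprint is exactly affine in the
contaminant count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import SampleManifest, Spectrum, write_manifest, write_spectrum

# Mixture series emulated by the presets: contaminant percentages of the
# calibration designs (pure populations appended where noted).
MEF28_FRACTIONS = (
    0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0,
    10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0, 70.0,
    80.0, 90.0,
)
MESC34_FRACTIONS = (
    0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0,
    9.0, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0,
    55.0, 60.0, 65.0, 70.0, 75.0, 80.0, 85.0, 90.0,
)


@dataclass
class ComponentProfile:
    """Per-cell fingerprint of one cell type: peak locations (Da/e), base
    intensities (arbitrary units per reference cell load), Gaussian widths
    (Da), and which peaks are designated unique markers."""

    label: str
    mz: np.ndarray
    intensity: np.ndarray
    width: np.ndarray
    is_marker: np.ndarray  # designated unique markers (subset of unique peaks)
    shared_mz: np.ndarray  # locations shared with the other component

    @property
    def marker_mz(self) -> np.ndarray:
        return self.mz[self.is_marker]

    @property
    def unique_mz(self) -> np.ndarray:
        shared = set(np.round(self.shared_mz, 6))
        mask = np.array([np.round(m, 6) not in shared for m in self.mz])
        return self.mz[mask]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the calibration designs: technical pentaplicates,
    mostly-shared fingerprints with a few unique markers, a concave
    saturating response (gamma < 1) with ionization cross-suppression, and
    modest replicate-level noise.
    """

    n_peaks: int = 24              # peaks per component profile
    shared_fraction: float = 0.75  # fraction of locations shared by A and B
    shared_contrast: float = 0.3   # A-vs-B abundance contrast on shared peaks
    n_markers: int = 4             # designated unique markers per component
    marker_intensity_lo: float = 0.5  # markers are prominent peaks
    total: int = 1_000_000         # cells per sample
    designs: tuple = ()            # ((n_cells_A, n_cells_B), ...)
    replicates: int = 5
    gamma: float = 0.6             # saturation exponent; 1 = linear response
    suppression: float = 5e-7     # per-cell cross-suppression strength s
    sat_k: float = 0.5             # saturation half-constant K
    jitter_sd: float = 1.5         # global m/z shift per replicate (Da)
    baseline_amplitude: float = 0.05
    mult_noise_cv: float = 0.03    # per-peak multiplicative noise CV
    add_noise_sd: float = 2e-3     # additive noise SD (intensity units)
    mz_lo: float = 2000.0
    mz_hi: float = 20000.0
    n_raw_points: int = 18000      # points of the irregular raw axis
    min_peak_separation: float = 40.0
    seed: int = 0
    stream: int = 0                # noise-stream namespace (validation sets
                                   # share profiles with seed but not noise)

    def __post_init__(self) -> None:
        if self.n_peaks < 10:
            raise ParameterError("n_peaks must be >= 10")
        if not 0.7 <= self.shared_fraction < 1.0:
            raise ParameterError("shared_fraction must be in [0.7, 1)")
        if self.n_markers < 2:
            raise ParameterError("each component needs >= 2 unique markers")
        n_unique = self.n_peaks - round(self.shared_fraction * self.n_peaks)
        if n_unique < self.n_markers:
            raise ParameterError(
                f"only {n_unique} unique peaks per component but "
                f"{self.n_markers} markers requested"
            )
        if not 0 <= self.shared_contrast <= 1:
            raise ParameterError("shared_contrast must be in [0, 1]")
        for name in ("jitter_sd", "baseline_amplitude", "mult_noise_cv",
                     "add_noise_sd", "suppression"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        n_locs = self.n_peaks + n_unique
        # locations are placed in [mz_lo + 100, mz_hi - 500]
        span = (self.mz_hi - 500.0) - (self.mz_lo + 100.0)
        if n_locs * self.min_peak_separation >= span:
            raise ParameterError(
                f"{n_locs} peak locations with separation "
                f"{self.min_peak_separation} Da do not fit in {span} Da"
            )

    def noiseless(self) -> "GeneratorConfig":
        """Copy with every stochastic distortion switched off (the
        saturating response is kept)."""
        d = asdict(self)
        d.update(jitter_sd=0.0, baseline_amplitude=0.0, mult_noise_cv=0.0,
                 add_noise_sd=0.0)
        return GeneratorConfig(**d)

    def linear(self) -> "GeneratorConfig":
        """Copy in the exactly linear limit: identity response, no
        suppression, no noise."""
        d = asdict(self)
        d.update(gamma=1.0, suppression=0.0, jitter_sd=0.0,
                 baseline_amplitude=0.0, mult_noise_cv=0.0, add_noise_sd=0.0)
        return GeneratorConfig(**d)


def _designs_from_fractions(fractions, total: int) -> tuple:
    designs = []
    for f in fractions:
        n_b = int(round(f / 100.0 * total))
        designs.append((total - n_b, n_b))
    return tuple(designs)


def preset_config(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Named study designs.

    * ``mef28``  — 28 mixtures + both pures, total 1e6 cells, pentaplicates
      (host + fibroblast-feeder analogue).
    * ``mesc34`` — 34 mixtures + both pures, total 0.5e6 cells,
      pentaplicates (host + closely related stem-cell analogue).
    * ``valid50`` — 50 independent validation mixtures, total 1e6 cells,
      single replicate, no pures.
    """
    if name == "mef28":
        total = 1_000_000
        fractions = (0.0,) + MEF28_FRACTIONS + (100.0,)
        reps = 5
    elif name == "mesc34":
        total = 500_000
        fractions = (0.0,) + MESC34_FRACTIONS + (100.0,)
        reps = 5
    elif name == "valid50":
        total = 1_000_000
        fractions = tuple(np.geomspace(0.3, 95.0, 50))
        reps = 1
    else:
        raise ParameterError(f"unknown preset {name!r}")
    params = dict(
        total=total,
        designs=_designs_from_fractions(fractions, total),
        replicates=reps,
        seed=seed,
        # independent validation samples share the cell-type profiles (same
        # seed) but none of the per-spot noise draws of the training sets
        stream=1 if name == "valid50" else 0,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def _spread_locations(rng, n: int, lo: float, hi: float, sep: float) -> np.ndarray:
    """n sorted locations in [lo, hi] with pairwise separation >= sep."""
    slack = (hi - lo) - (n - 1) * sep
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + sep * np.arange(n)


def make_component_profiles(
    config: GeneratorConfig,
) -> tuple[ComponentProfile, ComponentProfile]:
    """Seeded profiles for host A and contaminant B.

    A and B share ``shared_fraction`` of peak locations (with independent
    per-component abundances); the rest are unique, the first ``n_markers``
    of each designated markers.  All locations are at least
    ``min_peak_separation`` apart, so markers sit >= 20 Da from any shared
    peak.  Profiles are scaled to equal total ion yield per cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_shared = round(config.shared_fraction * config.n_peaks)
    n_unique = config.n_peaks - n_shared
    n_locs = n_shared + 2 * n_unique
    locs = _spread_locations(
        rng, n_locs, config.mz_lo + 100.0, config.mz_hi - 500.0,
        config.min_peak_separation,
    )
    assignment = rng.permutation(n_locs)
    shared = np.sort(locs[assignment[:n_shared]])
    uniq_a = np.sort(locs[assignment[n_shared:n_shared + n_unique]])
    uniq_b = np.sort(locs[assignment[n_shared + n_unique:]])
    # common abundance of shared peaks, perturbed per component by the
    # configured contrast (contrast 0: shared peaks identical in A and B,
    # so only the unique peaks track the mixture composition)
    shared_base = rng.uniform(0.1, 1.0, size=n_shared)
    c = config.shared_contrast
    shared_int = {
        "A": shared_base * (1.0 + c * rng.uniform(-1.0, 1.0, size=n_shared)),
        "B": shared_base * (1.0 + c * rng.uniform(-1.0, 1.0, size=n_shared)),
    }
    # the designated markers (first n_markers of each unique set) are
    # prominent peaks, as usable biomarker peaks are in practice
    def draw_unique() -> np.ndarray:
        out = rng.uniform(0.1, 1.0, size=n_unique)
        out[: config.n_markers] = rng.uniform(
            config.marker_intensity_lo, 1.0, size=config.n_markers
        )
        return out

    uniq_int = {"A": draw_unique(), "B": draw_unique()}

    def build(label: str, uniq: np.ndarray) -> ComponentProfile:
        mz = np.concatenate([shared, uniq])
        inten = np.concatenate([shared_int[label], uniq_int[label]])
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        # Gaussian sigma grows with m/z as in low-resolution linear TOF
        width = np.maximum(mz / 2500.0, 4.0)
        # equal total ion current per cell for A and B (area-weighted with
        # one shared constant), so sum-normalization keeps the linear
        # limit exactly affine
        target = 0.4 * len(mz) * 6.0
        inten *= target / float(inten @ width)
        marker_set = set(np.round(uniq[: config.n_markers], 6))
        is_marker = np.array([np.round(m, 6) in marker_set for m in mz])
        return ComponentProfile(
            label=label, mz=mz, intensity=inten, width=width,
            is_marker=is_marker, shared_mz=shared.copy(),
        )

    return build("A", uniq_a), build("B", uniq_b)


def _response(u: np.ndarray, full: np.ndarray, gamma: float, k: float) -> np.ndarray:
    """Saturating intensity response, per peak relative to its own
    full-load amplitude ``full``: r(u) = full * (1+k) x^gamma / (x^gamma + k)
    with x = u/full.  Identity when gamma == 1 (the documented linear
    switch).  Strongly concave at low loadings — a small contaminant
    fraction yields a disproportionately visible marker peak."""
    if gamma == 1.0:
        return u
    x = np.divide(u, full, where=full > 0, out=np.zeros_like(u))
    xg = np.power(x, gamma, where=x > 0, out=np.zeros_like(x))
    return full * (1.0 + k) * xg / (xg + k)


def make_raw_axis(config: GeneratorConfig) -> np.ndarray:
    """The instrument's irregular digitization axis, fixed per dataset
    (derived from the config seed, shared by all replicates)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lo, hi = config.mz_lo - 20.0, config.mz_hi + 20.0
    steps = rng.uniform(0.6, 1.4, size=config.n_raw_points)
    return lo + np.cumsum(steps) * (hi - lo) / steps.sum()


def render_mixture_spectrum(
    profiles: tuple[ComponentProfile, ComponentProfile],
    design: tuple[int, int],
    config: GeneratorConfig,
    replicate_seed,
    sample_id: str = "",
    replicate: int = 1,
    axis: np.ndarray | None = None,
) -> Spectrum:
    """Render one raw spectrum of the mixture ``design = (n_A, n_B)``.

    ``axis`` is the raw m/z axis; by default it is rebuilt from the config
    seed via :func:`make_raw_axis` (one digitizer per dataset)."""
    prof_a, prof_b = profiles
    n_a, n_b = design
    if n_a < 0 or n_b < 0:
        raise ValidationError("cell counts must be non-negative")
    total = n_a + n_b
    if total <= 0:
        raise ValidationError("design total must be positive")
    rng = np.random.default_rng(replicate_seed)

    # union of peak locations: per-cell linear loading u and the full-load
    # amplitude (the larger of the two per-cell intensities) per peak
    contributions: dict[float, list[float]] = {}
    for prof, count_self, count_other in (
        (prof_a, n_a, n_b), (prof_b, n_b, n_a),
    ):
        supp = 1.0 / (1.0 + config.suppression * count_other)
        for loc, inten, width in zip(prof.mz, prof.intensity, prof.width):
            key = round(float(loc), 9)
            rec = contributions.setdefault(key, [0.0, width, 0.0])
            rec[0] += count_self * inten * supp
            rec[2] = max(rec[2], inten)
    locs = np.array(sorted(contributions))
    u = np.array([contributions[k][0] for k in locs]) / total
    widths = np.array([contributions[k][1] for k in locs])
    full = np.array([contributions[k][2] for k in locs])
    amps = _response(u, full, config.gamma, config.sat_k)
    if config.mult_noise_cv > 0:
        cv = config.mult_noise_cv
        amps = amps * rng.lognormal(-0.5 * cv**2, cv, size=len(amps))
    shift = rng.normal(0.0, config.jitter_sd) if config.jitter_sd > 0 else 0.0

    if axis is None:
        axis = make_raw_axis(config)
    y = np.zeros_like(axis)
    for loc, amp, w in zip(locs + shift, amps, widths):
        if amp <= 0:
            continue
        i0, i1 = np.searchsorted(axis, [loc - 6 * w, loc + 6 * w])
        if i0 >= i1:
            continue
        seg = axis[i0:i1]
        y[i0:i1] += amp * np.exp(-0.5 * ((seg - loc) / w) ** 2)
    if config.baseline_amplitude > 0:
        y += config.baseline_amplitude * np.exp(-(axis - config.mz_lo) / 3000.0)
    if config.add_noise_sd > 0:
        y += rng.normal(0.0, config.add_noise_sd, size=len(axis))
    np.clip(y, 0.0, None, out=y)
    return Spectrum(axis, y, sample_id=sample_id, replicate=replicate, stage="raw")


def generate_spectra(
    config: GeneratorConfig,
) -> tuple[list[Spectrum], SampleManifest, dict]:
    """Render the whole calibration dataset in memory.

    Returns the raw spectra (manifest order), the manifest and a ground
    truth dictionary (designs plus config snapshot).  Fully determined by
    ``config.seed``.
    """
    if not config.designs:
        raise ParameterError("config.designs is empty")
    profiles = make_component_profiles(config)
    axis = make_raw_axis(config)
    spectra: list[Spectrum] = []
    rows = []
    for i, (n_a, n_b) in enumerate(config.designs):
        if n_a + n_b != config.total:
            raise ValidationError(
                f"design {i}: {n_a} + {n_b} != declared total {config.total}"
            )
        sample_id = f"mix{i:03d}"
        for rep in range(1, config.replicates + 1):
            child = np.random.SeedSequence([config.seed, 2, config.stream, i, rep])
            spectra.append(
                render_mixture_spectrum(
                    profiles, (n_a, n_b), config, child,
                    sample_id=sample_id, replicate=rep, axis=axis,
                )
            )
            rows.append({
                "sample_id": sample_id,
                "file": f"{sample_id}_r{rep}.tsv",
                "n_cells_A": n_a,
                "n_cells_B": n_b,
                "replicate": rep,
            })
    manifest = SampleManifest(pd.DataFrame(rows), total=config.total)
    truth = {
        "designs": [list(d) for d in config.designs],
        "total": config.total,
        "replicates": config.replicates,
        "marker_mz_A": profiles[0].marker_mz.tolist(),
        "marker_mz_B": profiles[1].marker_mz.tolist(),
        "config": asdict(config),
    }
    return spectra, manifest, truth


def make_calibration_dataset(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[SampleManifest, dict]:
    """Write the dataset to disk: one TSV spectrum per file, manifest.csv,
    ground_truth.json (designs + config snapshot)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra, manifest, truth = generate_spectra(config)
    for spec, file in zip(spectra, manifest.table["file"]):
        write_spectrum(spec, out_dir / file, format="tsv")
    write_manifest(manifest, out_dir / "manifest.csv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest, truth
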