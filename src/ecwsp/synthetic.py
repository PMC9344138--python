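"""Synthetic 5-class Vis-NIR absorbance spectra with known ground truth.

Real wine-like Vis-NIR spectra are dominated by two strong water absorption
bands near 1450 and 1930 nm that are common to every class; what separates
brands is a set of weak, localised differences in the visible region
(400-700 nm, pigments) and the combination-frequency region (2100-2400 nm).
The generator emulates exactly that structure phenomenologically:

``spectrum = sum(shared Gaussian peaks)
           + sum(class-specific Gaussian band offsets)
           + per-bottle constant baseline shift
           + correlated noise``

Class-specific bands are truncated at four widths, so outside a band's
support the class means are *exactly* equal — the informative wavelengths
are known by construction. Correlated noise (white noise smoothed with a
Gaussian kernel and rescaled to the target standard deviation) reproduces
the wavelength-to-wavelength autocorrelation that violates the naive-Bayes
independence assumption; the correlation of neighbouring points at distance
``d`` nm is ``exp(-d^2 / (2 L^2))`` for correlation length ``L``.

Samples follow a bottle / sample / replicate hierarchy: every bottle draws
one baseline offset shared by all its spectra, so grouped splitting is
genuinely necessary to avoid leakage. A class may be declared
*heterogeneous* (the "interference" class): each of its bottles then draws
its own band amplitudes from a stated range instead of using fixed
per-class offsets, emulating a catch-all class of assorted brands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigError
from .io import (
    META_COLUMNS,
    SpectralDataset,
    WavelengthGrid,
    concatenate_datasets,
)

#: class-specific bands are evaluated only within this many widths of centre
BAND_SUPPORT_WIDTHS = 4.0


@dataclass(frozen=True)
class Peak:
    """A Gaussian absorbance peak shared by every class."""

    center_nm: float
    width_nm: float
    amplitude: float  # AU at centre


@dataclass(frozen=True)
class InformativeBand:
    """A class-discriminating Gaussian band with per-class amplitude offsets."""

    center_nm: float
    width_nm: float
    offsets: tuple  # AU per class, config.class order
    hetero_range: tuple | None = None  # (lo, hi) AU for heterogeneous bottles


@dataclass(frozen=True)
class SyntheticConfig:
    grid: WavelengthGrid
    class_labels: tuple  # e.g. (1, 2, 3, 4, 5)
    shared_peaks: tuple  # of Peak
    informative_bands: tuple  # of InformativeBand
    noise_sd: float = 0.02  # AU, per wavelength after smoothing
    noise_correlation_length: float = 8.0  # nm; <= 0 gives white noise
    bottle_offset_sd: float = 0.01  # AU, constant per bottle
    bottles_per_class: int = 20
    samples_per_bottle: int = 5
    replicates_per_sample: int = 3
    seed: int = 0
    heterogeneous_classes: tuple = ()  # labels whose bottles draw own offsets
    bottle_prefixes: tuple | None = None  # per class; default "C<label>"

    def __post_init__(self) -> None:
        k = len(self.class_labels)
        if k < 1:
            raise ConfigError("need at least one class")
        if self.noise_sd < 0 or self.bottle_offset_sd < 0:
            raise ConfigError("noise levels must be non-negative")
        if min(self.bottles_per_class, self.samples_per_bottle, self.replicates_per_sample) < 1:
            raise ConfigError("hierarchy counts must be >= 1")
        for band in self.informative_bands:
            if len(band.offsets) != k:
                raise ConfigError(
                    f"band at {band.center_nm} nm has {len(band.offsets)} offsets "
                    f"for {k} classes"
                )
            if not (self.grid.start_nm <= band.center_nm <= self.grid.end_nm):
                raise ConfigError(f"band centre {band.center_nm} nm is off the grid")
            if k >= 2 and len(set(band.offsets)) < 2:
                raise ConfigError(
                    f"band at {band.center_nm} nm does not separate any two classes"
                )
        for peak in self.shared_peaks:
            if not (self.grid.start_nm <= peak.center_nm <= self.grid.end_nm):
                raise ConfigError(f"peak centre {peak.center_nm} nm is off the grid")
        if self.bottle_prefixes is not None and len(self.bottle_prefixes) != k:
            raise ConfigError("bottle_prefixes must have one entry per class")


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _band_profile(wl: np.ndarray, band: InformativeBand) -> np.ndarray:
    """Truncated Gaussian: exactly zero outside +/- BAND_SUPPORT_WIDTHS widths."""
    prof = _gaussian(wl, band.center_nm, band.width_nm)
    prof[np.abs(wl - band.center_nm) > BAND_SUPPORT_WIDTHS * band.width_nm] = 0.0
    return prof


def _correlated_noise(
    rng: np.random.Generator, shape: tuple, grid: WavelengthGrid, sd: float, length_nm: float
) -> np.ndarray:
    """White noise smoothed to autocorrelation exp(-d^2/(2 L^2)), sd per point."""
    eps = rng.standard_normal(shape)
    if sd == 0.0:
        return np.zeros(shape)
    if length_nm <= 0:
        return sd * eps
    # kernel sd L/sqrt(2) yields the stated Gaussian autocorrelation of scale L
    s_pts = (length_nm / np.sqrt(2.0)) / grid.step_nm
    smooth = gaussian_filter1d(eps, s_pts, axis=-1, mode="wrap")
    radius = int(4.0 * s_pts + 0.5)  # matches the filter's default truncation
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / s_pts) ** 2)
    k /= k.sum()
    return smooth * (sd / np.sqrt((k**2).sum()))


def generate(config: SyntheticConfig) -> tuple[SpectralDataset, np.ndarray]:
    """Generate a dataset plus the ground-truth informative wavelengths.

    Returns the dataset (set tags ``unassigned``) and, for each informative
    band, the grid wavelength nearest its centre. Bit-identical for a given
    config and seed.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    wl = grid.wavelengths
    k = len(config.class_labels)

    base = np.zeros_like(wl)
    for peak in config.shared_peaks:
        base += peak.amplitude * _gaussian(wl, peak.center_nm, peak.width_nm)
    band_profiles = [_band_profile(wl, b) for b in config.informative_bands]

    reps = config.replicates_per_sample
    rows_meta: list[tuple] = []
    means: list[np.ndarray] = []
    for ci, label in enumerate(config.class_labels):
        prefix = (
            config.bottle_prefixes[ci]
            if config.bottle_prefixes is not None
            else f"C{label}"
        )
        hetero = label in config.heterogeneous_classes
        for b in range(1, config.bottles_per_class + 1):
            bottle_id = f"{prefix}-B{b:02d}"
            offset = rng.normal(0.0, config.bottle_offset_sd) if config.bottle_offset_sd > 0 else 0.0
            amps = []
            for band in config.informative_bands:
                if hetero:
                    lo, hi = (
                        band.hetero_range
                        if band.hetero_range is not None
                        else (min(band.offsets), max(band.offsets))
                    )
                    amps.append(rng.uniform(lo, hi))
                else:
                    amps.append(band.offsets[ci])
            mean = base + offset
            for amp, prof in zip(amps, band_profiles):
                mean = mean + amp * prof
            for s in range(1, config.samples_per_bottle + 1):
                sample_id = f"{bottle_id}-S{s}"
                for r in range(1, reps + 1):
                    rows_meta.append((int(label), bottle_id, sample_id, r, "unassigned"))
                    means.append(mean)

    mean_matrix = np.vstack(means)
    noise = _correlated_noise(
        rng,
        mean_matrix.shape,
        grid,
        config.noise_sd,
        config.noise_correlation_length,
    )
    absorbance = mean_matrix + noise
    meta = pd.DataFrame(rows_meta, columns=list(META_COLUMNS))
    dataset = SpectralDataset(grid, absorbance, meta)
    truth = np.array(
        [wl[np.argmin(np.abs(wl - b.center_nm))] for b in config.informative_bands]
    )
    return dataset, truth


# -------------------------------------------------------------- configurations

def _coded_offsets(separation_au: float, k: int = 5) -> list[tuple]:
    """Band offsets that make every band *necessary* for full separation.

    Classes carry a binary code over three bands — (000, 100, 010, 001,
    111) — scaled by the separation amplitude: every class pair differs on
    at least one band and dropping any band merges at least one pair.
    """
    if k != 5:
        raise ConfigError("the coded layout is defined for 5 classes")
    codes = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]
    return [tuple(separation_au * c[b] for c in codes) for b in range(3)]


def separation_au(noise_sd: float, bottle_offset_sd: float, n_sigma: float = 3.0) -> float:
    """Band amplitude step giving an n-sigma class separation at band centre."""
    return n_sigma * float(np.hypot(noise_sd, bottle_offset_sd))


def default_config(seed: int = 0) -> SyntheticConfig:
    """Full-range wine-like conditions: strong shared water bands near 1450
    and 1930 nm, weak class differences in the visible and the
    combination-frequency region, 20 bottles x 5 samples x 3 replicates
    per class."""
    noise_sd, bottle_sd = 0.02, 0.002
    sep = separation_au(noise_sd, bottle_sd)
    b1, b2, b3 = _coded_offsets(sep)
    return SyntheticConfig(
        grid=WavelengthGrid(400.0, 2498.0, 2.0),
        class_labels=(1, 2, 3, 4, 5),
        shared_peaks=(
            Peak(1450.0, 70.0, 1.2),
            Peak(1930.0, 90.0, 1.6),
            Peak(980.0, 50.0, 0.45),
        ),
        informative_bands=(
            InformativeBand(450.0, 25.0, b1),
            InformativeBand(600.0, 30.0, b2),
            InformativeBand(2270.0, 50.0, b3),
        ),
        noise_sd=noise_sd,
        noise_correlation_length=4.0,
        bottle_offset_sd=bottle_sd,
        seed=seed,
    )


def recovery_config(seed: int = 0) -> SyntheticConfig:
    """Reduced-grid benchmark for wavelength-recovery studies.

    400-1000 nm at 2 nm (301 points), 5 classes, three informative bands at
    600 / 700 / 800 nm with a 3-sigma class separation at band centre and
    correlated noise; 8 bottles x 3 samples x 3 replicates per class keeps a
    full exhaustive search fast enough to repeat over many seeds. The band
    spacing (100 nm) and width (25 nm) were fixed by a design calculation:
    an equidistant model with an 8-10 nm gap spanning the three bands
    carries a pairwise discriminant deflection of ~6-7 noise standard
    deviations for class pairs that differ on a single band, so a
    well-chosen model separates the classes essentially perfectly while
    models that miss a band cannot.
    """
    noise_sd, bottle_sd = 0.02, 0.002
    sep = separation_au(noise_sd, bottle_sd)
    b1, b2, b3 = _coded_offsets(sep)
    return SyntheticConfig(
        grid=WavelengthGrid(400.0, 1000.0, 2.0),
        class_labels=(1, 2, 3, 4, 5),
        shared_peaks=(
            Peak(970.0, 40.0, 0.9),
            Peak(500.0, 150.0, 0.35),
        ),
        informative_bands=(
            InformativeBand(600.0, 25.0, b1),
            InformativeBand(700.0, 25.0, b2),
            InformativeBand(800.0, 25.0, b3),
        ),
        noise_sd=noise_sd,
        noise_correlation_length=4.0,
        bottle_offset_sd=bottle_sd,
        bottles_per_class=8,
        samples_per_bottle=3,
        replicates_per_sample=3,
        seed=seed,
    )


def make_reference_dataset(seed: int = 0) -> SpectralDataset:
    """The full five-brand study layout: 1533 spectra.

    Four identification classes (20 bottles x 5 samples x 3 replicates =
    300 spectra each) plus a heterogeneous interference class assembled
    from 21 "commercial" bottles (3 samples each, 189 spectra) and 48
    "home-brew" bottles (1 sample each, 144 spectra; 333 in total). Each
    interference bottle draws its own band amplitudes from a widened range,
    giving the class its elevated within-class spread.
    """
    base = default_config(seed)
    sep = separation_au(base.noise_sd, base.bottle_offset_sd)
    hetero_span = (-0.25 * sep, 1.25 * sep)

    def _hetero_bands(bands: Sequence[InformativeBand], k: int) -> tuple:
        return tuple(
            replace(b, offsets=tuple([0.0] * k), hetero_range=hetero_span)
            for b in bands
        )

    ident = replace(
        base,
        class_labels=(1, 2, 3, 4),
        informative_bands=tuple(
            replace(b, offsets=b.offsets[:4]) for b in base.informative_bands
        ),
        seed=_child_seed(seed, 0),
    )
    commercial = replace(
        base,
        class_labels=(5,),
        informative_bands=_hetero_bands(base.informative_bands, 1),
        heterogeneous_classes=(5,),
        bottles_per_class=21,
        samples_per_bottle=3,
        bottle_prefixes=("V-COM",),
        seed=_child_seed(seed, 1),
    )
    home = replace(
        base,
        class_labels=(5,),
        informative_bands=_hetero_bands(base.informative_bands, 1),
        heterogeneous_classes=(5,),
        bottles_per_class=48,
        samples_per_bottle=1,
        bottle_prefixes=("V-HOME",),
        seed=_child_seed(seed, 2),
    )
    parts = [generate(c)[0] for c in (ident, commercial, home)]
    ds = concatenate_datasets(parts)
    ds.validate()
    return ds


def _child_seed(seed: int, index: int) -> int:
    """Derived sub-seed, kept below 2**31."""
    return int((seed * 1_000_003 + index) % (2**31 - 1))


# ------------------------------------------------------- config serialisation

def config_to_dict(config: SyntheticConfig) -> dict:
    """Plain-dict form of a config (YAML-friendly)."""
    g = config.grid
    return {
        "grid": {"start_nm": g.start_nm, "end_nm": g.end_nm, "step_nm": g.step_nm},
        "class_labels": list(config.class_labels),
        "shared_peaks": [
            {"center_nm": p.center_nm, "width_nm": p.width_nm, "amplitude": p.amplitude}
            for p in config.shared_peaks
        ],
        "informative_bands": [
            {
                "center_nm": b.center_nm,
                "width_nm": b.width_nm,
                "offsets": list(b.offsets),
                **({"hetero_range": list(b.hetero_range)} if b.hetero_range else {}),
            }
            for b in config.informative_bands
        ],
        "noise_sd": config.noise_sd,
        "noise_correlation_length": config.noise_correlation_length,
        "bottle_offset_sd": config.bottle_offset_sd,
        "bottles_per_class": config.bottles_per_class,
        "samples_per_bottle": config.samples_per_bottle,
        "replicates_per_sample": config.replicates_per_sample,
        "seed": config.seed,
        "heterogeneous_classes": list(config.heterogeneous_classes),
        **(
            {"bottle_prefixes": list(config.bottle_prefixes)}
            if config.bottle_prefixes is not None
            else {}
        ),
    }


def config_from_dict(d: dict) -> SyntheticConfig:
    """Inverse of :func:`config_to_dict`; unknown keys raise ConfigError."""
    d = dict(d)
    try:
        g = d.pop("grid")
        grid = WavelengthGrid(float(g["start_nm"]), float(g["end_nm"]), float(g["step_nm"]))
        peaks = tuple(
            Peak(float(p["center_nm"]), float(p["width_nm"]), float(p["amplitude"]))
            for p in d.pop("shared_peaks", [])
        )
        bands = tuple(
            InformativeBand(
                float(b["center_nm"]),
                float(b["width_nm"]),
                tuple(float(x) for x in b["offsets"]),
                tuple(float(x) for x in b["hetero_range"]) if b.get("hetero_range") else None,
            )
            for b in d.pop("informative_bands", [])
        )
        labels = tuple(int(x) for x in d.pop("class_labels"))
    except KeyError as exc:
        raise ConfigError(f"synthetic config is missing key {exc}") from None
    hetero = tuple(int(x) for x in d.pop("heterogeneous_classes", ()))
    prefixes = d.pop("bottle_prefixes", None)
    known = {
        "noise_sd",
        "noise_correlation_length",
        "bottle_offset_sd",
        "bottles_per_class",
        "samples_per_bottle",
        "replicates_per_sample",
        "seed",
    }
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown synthetic config key(s) {sorted(unknown)}")
    return SyntheticConfig(
        grid=grid,
        class_labels=labels,
        shared_peaks=peaks,
        informative_bands=bands,
        heterogeneous_classes=hetero,
        bottle_prefixes=tuple(prefixes) if prefixes is not None else None,
        **{k: d[k] for k in d},
    )
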