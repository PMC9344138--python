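"""Gaussian naive-Bayes core for spectral discrimination.

The classifier treats the absorbance at each selected wavelength as an
independent normal variate given the class. Fitting estimates, per class
``k`` and grid wavelength ``i``, the mean ``mu[k, i]`` and sample standard
deviation ``sigma[k, i]`` of the calibration absorbances. The class
log-conditional of a spectrum over a wavelength subset ``S`` is the sum of
per-wavelength normal log-densities — the log of the naive product of
conditionals, computed in log space so that products over many wavelengths
cannot overflow or underflow. Posteriors follow from Bayes' rule with a
log-sum-exp stabilised normalisation; the decision is the posterior argmax,
ties broken toward the smallest class label.

For wavelength searches over many subsets, :func:`precompute_cube` caches
every per-(spectrum, class, wavelength) log-density once; any subset score
is then a contiguous sum over the cube's last axis, bit-identical to the
direct evaluation (both reduce a C-contiguous ``(..., s)`` array over its
last axis, so the floating-point summation order is the same).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FitError
from .io import SpectralDataset, WavelengthGrid

_LOG_2PI = float(np.log(2.0 * np.pi))

#: default lower bound on per-wavelength standard deviations (absorbance units)
DEFAULT_SD_FLOOR = 1e-6


@dataclass
class ClassStats:
    """Per-class, per-wavelength normal parameters of the conditional model.

    Fitted once over the full grid; any wavelength-subset model simply reads
    its columns.
    """

    grid: WavelengthGrid
    class_ids: np.ndarray  # (K,) ascending class labels
    mu: np.ndarray  # (K, p)
    sigma: np.ndarray  # (K, p), floored at sd_floor
    sd_floor: float

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.shape != (
            len(self.class_ids),
            self.grid.point_count,
        ):
            raise ConfigError("mu/sigma shapes do not match (K, point_count)")
        if not (self.sd_floor > 0):
            raise ConfigError("sd_floor must be positive")
        if np.any(self.sigma < self.sd_floor):
            raise ConfigError("sigma entries below sd_floor")

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    def fingerprint(self) -> str:
        """Stable hash of the fitted parameters (audit aid: detects refits)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.mu.tobytes())
        h.update(self.sigma.tobytes())
        return h.hexdigest()

    # -------------------------------------------------------------- CSV audit
    def to_frame(self) -> pd.DataFrame:
        cols = {"wavelength_nm": self.grid.wavelengths}
        for j, k in enumerate(self.class_ids):
            cols[f"mu_{k}"] = self.mu[j]
            cols[f"sigma_{k}"] = self.sigma[j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# sd_floor={self.sd_floor!r}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, sd_floor: float = DEFAULT_SD_FLOOR) -> "ClassStats":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("# sd_floor="):
                sd_floor = float(first.split("=", 1)[1])
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        grid = WavelengthGrid.from_wavelengths(df["wavelength_nm"].to_numpy())
        ks = sorted(int(c[3:]) for c in df.columns if c.startswith("mu_"))
        mu = np.vstack([df[f"mu_{k}"].to_numpy() for k in ks])
        sigma = np.vstack([df[f"sigma_{k}"].to_numpy() for k in ks])
        return cls(grid, np.asarray(ks), mu, sigma, sd_floor)


@dataclass(frozen=True)
class PriorSpec:
    """Class prior probabilities, either proportional to calibration size or equal."""

    class_ids: tuple
    values: tuple  # P(Class = k), same order as class_ids
    mode: str = "proportional"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise ConfigError("prior probabilities must be positive")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ConfigError(f"priors sum to {v.sum()!r}, not 1")

    @property
    def log_values(self) -> np.ndarray:
        return np.log(np.asarray(self.values, dtype=float))

    @classmethod
    def proportional(cls, labels: Sequence[int]) -> "PriorSpec":
        """Priors proportional to per-class calibration spectrum counts."""
        ks, counts = np.unique(np.asarray(labels), return_counts=True)
        v = counts / counts.sum()
        v = v / v.sum()
        return cls(tuple(int(k) for k in ks), tuple(float(x) for x in v), "proportional")

    @classmethod
    def equal(cls, class_ids: Sequence[int]) -> "PriorSpec":
        ks = sorted(int(k) for k in class_ids)
        k = len(ks)
        # make the probabilities sum to exactly 1.0 in floating point
        v = np.full(k, 1.0 / k)
        v[-1] = 1.0 - v[:-1].sum()
        return cls(tuple(ks), tuple(float(x) for x in v), "equal")

    @classmethod
    def for_stats(cls, stats: ClassStats, mode: str, calibration_labels=None) -> "PriorSpec":
        if mode == "equal":
            return cls.equal(stats.class_ids)
        if mode == "proportional":
            if calibration_labels is None:
                raise ConfigError("proportional priors need calibration labels")
            return cls.proportional(calibration_labels)
        raise ConfigError(f"unknown prior mode {mode!r}")


# ------------------------------------------------------------------ densities

def log_density(x, mu, sigma):
    """Natural log of the normal density; may be positive for small sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = (np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def fit(
    dataset: SpectralDataset,
    sd_floor: float = DEFAULT_SD_FLOOR,
    set_tag: str | None = "calibration",
) -> ClassStats:
    """Estimate per-class means and sample standard deviations (ddof=1).

    Only spectra carrying ``set_tag`` are used (pass ``None`` to use all
    rows). Standard deviations are floored at ``sd_floor`` so that
    zero-variance wavelengths cannot produce infinite densities.
    """
    ds = dataset if set_tag is None else dataset.subset(set_tag)
    if ds.n_spectra == 0:
        raise FitError("calibration set is empty")
    ks = np.unique(ds.class_labels)
    mu = np.empty((len(ks), ds.grid.point_count))
    sigma = np.empty_like(mu)
    for j, k in enumerate(ks):
        block = ds.absorbance[ds.class_labels == k]
        if block.shape[0] < 2:
            raise FitError(
                f"class {k} has {block.shape[0]} calibration spectrum(s); need >= 2"
            )
        mu[j] = block.mean(axis=0)
        sigma[j] = np.maximum(block.std(axis=0, ddof=1), sd_floor)
    return ClassStats(ds.grid, ks, mu, sigma, sd_floor)


def _subset_indices(stats: ClassStats, wavelengths_nm) -> np.ndarray:
    if wavelengths_nm is None:
        return np.arange(stats.grid.point_count, dtype=np.intp)
    idx = stats.grid.indices(wavelengths_nm)
    if idx.size == 0:
        raise ValueError("wavelength subset must be non-empty")
    return idx


def log_conditional(
    spectra: np.ndarray,
    stats: ClassStats,
    wavelengths_nm: Iterable[float] | None = None,
) -> np.ndarray:
    """ln P(spectrum | class) over a wavelength subset, shape (n, K).

    Equal analytically to the log of the per-wavelength density product; the
    summation runs over the last (contiguous) axis in ascending wavelength
    order, the same order the log-density cube uses.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    idx = _subset_indices(stats, wavelengths_nm)
    # (n, 1, s) against (K, s) -> (n, K, s), C-contiguous
    ld = log_density(X[:, None, idx], stats.mu[:, idx], stats.sigma[:, idx])
    return ld.sum(axis=-1)


def posterior(log_conditionals: np.ndarray, priors: PriorSpec) -> np.ndarray:
    """P(class | spectrum) by Bayes' rule, log-sum-exp stabilised; rows sum to 1."""
    lc = np.atleast_2d(np.asarray(log_conditionals, dtype=float))
    scores = lc + priors.log_values
    scores = scores - scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    out = w / w.sum(axis=1, keepdims=True)
    return out if np.asarray(log_conditionals).ndim == 2 else out[0]


def decision_scores(
    log_conditionals: np.ndarray,
    priors: PriorSpec | None,
    include_prior: bool = True,
) -> np.ndarray:
    """Per-class decision scores: log conditional plus (optionally) log prior."""
    lc = np.atleast_2d(np.asarray(log_conditionals, dtype=float))
    if include_prior:
        if priors is None:
            raise ConfigError("include_prior=True requires a PriorSpec")
        return lc + priors.log_values
    return lc


def predict(
    spectra: np.ndarray,
    stats: ClassStats,
    priors: PriorSpec | None = None,
    wavelengths_nm: Iterable[float] | None = None,
    include_prior: bool = True,
) -> np.ndarray:
    """Class label per spectrum; argmax ties break toward the smaller label.

    With ``include_prior=False`` the decision uses the bare log conditional
    (maximum-likelihood rule); the default adds the class log prior.
    """
    lc = log_conditional(spectra, stats, wavelengths_nm)
    scores = decision_scores(lc, priors, include_prior)
    return np.asarray(stats.class_ids)[np.argmax(scores, axis=1)]


def majority_vote(labels: np.ndarray, sample_ids: Sequence) -> np.ndarray:
    """Replace each spectrum's label by its sample's majority label.

    Ties go to the smallest label. Off by default everywhere; the standard
    classification unit is the individual spectrum.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    sample_ids = np.asarray(sample_ids)
    for sid in pd.unique(sample_ids):
        m = sample_ids == sid
        ks, counts = np.unique(labels[m], return_counts=True)
        out[m] = ks[np.argmax(counts)]
    return out


# ----------------------------------------------------------------- the cube

@dataclass
class LogDensityCube:
    """Cached per-(spectrum, class, wavelength) log densities.

    ``values`` has shape ``(n, K, p)`` (class axis before wavelength so that
    subset sums reduce the contiguous last axis). For any wavelength-index
    subset, :meth:`subset_log_conditional` equals
    :func:`log_conditional` bit-for-bit.
    """

    values: np.ndarray  # (n, K, p)
    class_ids: np.ndarray
    grid: WavelengthGrid

    def subset_log_conditional(self, idx: np.ndarray) -> np.ndarray:
        """Sum cube entries over the wavelength-index subset -> (n, K)."""
        idx = np.asarray(idx, dtype=np.intp)
        return self.values[:, :, idx].sum(axis=-1)


def precompute_cube(spectra: np.ndarray, stats: ClassStats) -> LogDensityCube:
    """Evaluate every log density once so subset scores become cheap sums."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    vals = log_density(X[:, None, :], stats.mu, stats.sigma)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite log density in cube (check sd_floor and inputs)")
    return LogDensityCube(np.ascontiguousarray(vals), np.asarray(stats.class_ids), stats.grid)
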