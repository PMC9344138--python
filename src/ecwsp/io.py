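"""Wide-format spectral tables, the wavelength grid, and grouped set splitting.

A dataset holds an absorbance matrix on a uniform wavelength grid together
with per-spectrum metadata: class label, bottle / sample / replicate
identifiers and a set tag (``calibration`` / ``prediction`` / ``validation``
/ ``unassigned``). All public interfaces speak physical wavelengths in nm;
column indices are an internal 0-based convention.

Splitting into calibration, prediction and validation sets is *grouped*: a
bottle's spectra always travel together, so the three replicate spectra of a
sample can never leak across sets and the prediction / validation sets
contain only bottles the classifier has never seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError, GridLookupError

META_COLUMNS = ("class_label", "bottle_id", "sample_id", "replicate_id", "set")
SET_TAGS = ("calibration", "prediction", "validation", "unassigned")

#: relative tolerance for deciding that a wavelength lies on the grid
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``start_nm, start_nm + step_nm, ..., end_nm``."""

    start_nm: float
    end_nm: float
    step_nm: float = 2.0

    def __post_init__(self) -> None:
        if not (self.step_nm > 0):
            raise ConfigError(f"grid step must be positive, got {self.step_nm}")
        if not (self.start_nm < self.end_nm):
            raise ConfigError(
                f"grid start {self.start_nm} must lie below end {self.end_nm}"
            )
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > _GRID_RTOL * max(1.0, abs(span)):
            raise ConfigError(
                f"grid span {self.start_nm}-{self.end_nm} is not an integer "
                f"multiple of the step {self.step_nm}"
            )

    @property
    def point_count(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.point_count)

    def index(self, wavelength_nm: float) -> int:
        """0-based column index of an on-grid wavelength."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > _GRID_RTOL * max(1.0, abs(pos)) or not (
            0 <= idx < self.point_count
        ):
            raise GridLookupError(
                f"wavelength {wavelength_nm} nm is not on the grid "
                f"{self.start_nm}-{self.end_nm} nm (step {self.step_nm})"
            )
        return idx

    def indices(self, wavelengths_nm: Iterable[float]) -> np.ndarray:
        return np.asarray([self.index(w) for w in wavelengths_nm], dtype=np.intp)

    @classmethod
    def from_wavelengths(cls, wavelengths: Sequence[float]) -> "WavelengthGrid":
        """Build a grid from strictly increasing, uniformly spaced wavelengths."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise FormatError("need at least two wavelength headers to fix the grid step")
        diffs = np.diff(wl)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise FormatError(
                f"wavelength headers not strictly increasing at ({wl[i]:g}, {wl[i + 1]:g})"
            )
        step = diffs[0]
        bad = np.abs(diffs - step) > _GRID_RTOL * step
        if np.any(bad):
            i = int(np.argmax(bad))
            raise FormatError(
                f"non-uniform wavelength spacing at ({wl[i]:g}, {wl[i + 1]:g}): "
                f"step {diffs[i]:g} differs from {step:g}"
            )
        return cls(float(wl[0]), float(wl[-1]), float(step))


def wavelength_index(grid: WavelengthGrid, wavelength_nm: float) -> int:
    """Module-level alias of :meth:`WavelengthGrid.index`."""
    return grid.index(wavelength_nm)


#: full Vis-NIR range of a scanning grating spectrometer: 400-2498 nm, 2 nm step
DEFAULT_GRID = WavelengthGrid(400.0, 2498.0, 2.0)


@dataclass
class SpectralDataset:
    """Absorbance matrix plus per-spectrum metadata.

    ``absorbance`` has one row per spectrum and one column per grid
    wavelength; ``meta`` carries the columns in :data:`META_COLUMNS`.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise DataError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != self.grid.point_count:
            raise DataError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.grid.point_count} wavelengths"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise FormatError(f"metadata is missing columns {missing}")
        if len(self.meta) != self.absorbance.shape[0]:
            raise DataError("metadata and absorbance row counts differ")
        self.meta = self.meta.reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    @property
    def class_ids(self) -> np.ndarray:
        return np.unique(self.class_labels)

    @property
    def set_tags(self) -> np.ndarray:
        return self.meta["set"].to_numpy()

    def subset(self, set_tag: str | None = None, mask: np.ndarray | None = None) -> "SpectralDataset":
        """Return the spectra with the given set tag (or boolean row mask)."""
        if mask is None:
            if set_tag not in SET_TAGS:
                raise ConfigError(f"unknown set tag {set_tag!r}")
            mask = self.set_tags == set_tag
        return SpectralDataset(
            self.grid,
            self.absorbance[mask],
            self.meta.loc[mask].reset_index(drop=True),
        )

    def validate(self) -> None:
        """Check dataset invariants; raise :class:`DataError` on violation."""
        if not np.isfinite(self.absorbance).all():
            row = int(np.argmax(~np.isfinite(self.absorbance).all(axis=1)))
            raise DataError(f"non-finite absorbance in spectrum row {row}")
        bad_tags = set(self.meta["set"]) - set(SET_TAGS)
        if bad_tags:
            raise DataError(f"unknown set tags {sorted(bad_tags)}")
        per_sample = self.meta.groupby("sample_id")[["bottle_id", "class_label"]].nunique()
        mixed = per_sample[(per_sample > 1).any(axis=1)]
        if len(mixed):
            raise DataError(
                f"sample {mixed.index[0]!r} spans multiple bottles or class labels"
            )


def concatenate_datasets(datasets: Sequence[SpectralDataset]) -> SpectralDataset:
    """Stack datasets that share a common wavelength grid."""
    if not datasets:
        raise ConfigError("nothing to concatenate")
    grid = datasets[0].grid
    for ds in datasets[1:]:
        if ds.grid != grid:
            raise ConfigError("datasets do not share a wavelength grid")
    return SpectralDataset(
        grid,
        np.vstack([ds.absorbance for ds in datasets]),
        pd.concat([ds.meta for ds in datasets], ignore_index=True),
    )


# --------------------------------------------------------------------- file IO

def _format_wavelength(w: float) -> str:
    return format(w, "g")


def read_dataset(
    path, grid_expectation: WavelengthGrid | None = None
) -> SpectralDataset:
    """Read a wide spectral CSV.

    The header must contain the metadata columns of :data:`META_COLUMNS`
    followed by strictly increasing, uniformly spaced numeric wavelength
    headers (nm). Leading ``#`` comment lines are ignored.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wl = np.asarray([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from None
    grid = WavelengthGrid.from_wavelengths(wl)
    if grid_expectation is not None and grid != grid_expectation:
        raise FormatError(
            f"{path}: grid {grid} does not match the expected {grid_expectation}"
        )
    absorbance = df[wl_cols].to_numpy(dtype=float)
    finite = np.isfinite(absorbance).all(axis=1)
    if not finite.all():
        row = int(np.argmax(~finite))
        raise DataError(f"{path}: non-finite absorbance in data row {row}")
    meta = df[list(META_COLUMNS)].copy()
    meta["class_label"] = meta["class_label"].astype(int)
    ds = SpectralDataset(grid, absorbance, meta)
    ds.validate()
    return ds


def write_dataset(dataset: SpectralDataset, path, header_comment: str | None = None) -> None:
    """Write the wide spectral CSV; floats round-trip at full precision."""
    cols = [_format_wavelength(w) for w in dataset.grid.wavelengths]
    spectra = pd.DataFrame(dataset.absorbance, columns=cols)
    out = pd.concat([dataset.meta[list(META_COLUMNS)], spectra], axis=1)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False, float_format="%.17g")


# ----------------------------------------------------------------- set splits

@dataclass(frozen=True)
class GroupAllocation:
    """Bottle counts for one class (optionally one bottle-id stratum)."""

    class_label: int
    n_calibration: int
    n_prediction: int
    n_validation: int
    bottle_prefix: str | None = None  # restrict to bottle ids with this prefix

    @property
    def total(self) -> int:
        return self.n_calibration + self.n_prediction + self.n_validation


@dataclass(frozen=True)
class SplitPlan:
    """Bottle-level allocation of every class to the three sets."""

    allocations: tuple[GroupAllocation, ...]
    seed: int = 0


def grouped_split(dataset: SpectralDataset, plan: SplitPlan) -> SpectralDataset:
    """Randomly assign whole bottles to calibration / prediction / validation.

    Every spectrum of a bottle receives the same set tag; allocation counts
    follow the plan exactly and the assignment is deterministic for a given
    plan seed. Returns a new dataset; the input is left untouched.
    """
    rng = np.random.default_rng(plan.seed)
    bottles = dataset.meta["bottle_id"].to_numpy()
    labels = dataset.class_labels

    covered_classes = {a.class_label for a in plan.allocations}
    present = set(int(c) for c in dataset.class_ids)
    uncovered = present - covered_classes
    if uncovered:
        raise ConfigError(f"split plan covers no allocation for class(es) {sorted(uncovered)}")

    tags = np.full(dataset.n_spectra, "", dtype=object)
    seen_bottles: set[str] = set()
    for alloc in plan.allocations:
        mask = labels == alloc.class_label
        if alloc.bottle_prefix is not None:
            mask &= np.char.startswith(bottles.astype(str), alloc.bottle_prefix)
        group = sorted(set(bottles[mask]))
        overlap = seen_bottles.intersection(group)
        if overlap:
            raise ConfigError(f"bottle(s) {sorted(overlap)[:3]} covered by two allocations")
        seen_bottles.update(group)
        if alloc.total != len(group):
            raise ConfigError(
                f"class {alloc.class_label}"
                + (f" (prefix {alloc.bottle_prefix!r})" if alloc.bottle_prefix else "")
                + f": plan allocates {alloc.total} bottles but {len(group)} are available"
            )
        order = rng.permutation(len(group))
        shuffled = [group[i] for i in order]
        assignment = (
            [("calibration", b) for b in shuffled[: alloc.n_calibration]]
            + [("prediction", b) for b in shuffled[alloc.n_calibration : alloc.n_calibration + alloc.n_prediction]]
            + [("validation", b) for b in shuffled[alloc.n_calibration + alloc.n_prediction :]]
        )
        for tag, bottle in assignment:
            tags[bottles == bottle] = tag

    if (tags == "").any():
        row = int(np.argmax(tags == ""))
        raise ConfigError(
            f"spectrum row {row} (bottle {bottles[row]!r}) matched no allocation"
        )
    meta = dataset.meta.copy()
    meta["set"] = tags.astype(str)
    return SpectralDataset(dataset.grid, dataset.absorbance.copy(), meta)


def reference_split_plan(seed: int = 0) -> SplitPlan:
    """Bottle allocation of the five-brand reference layout.

    Each of the four identification brands contributes 20 bottles split
    8 / 6 / 6; the interference class (label 5) is stratified into 21
    commercial bottles split 7 / 7 / 7 and 48 home-brew bottles split
    18 / 15 / 15, matching the bottle-id prefixes written by
    :func:`ecwsp.synthetic.make_reference_dataset`.
    """
    allocs = [GroupAllocation(k, 8, 6, 6) for k in (1, 2, 3, 4)]
    allocs.append(GroupAllocation(5, 7, 7, 7, bottle_prefix="V-COM"))
    allocs.append(GroupAllocation(5, 18, 15, 15, bottle_prefix="V-HOME"))
    return SplitPlan(tuple(allocs), seed=seed)


def uniform_split_plan(
    dataset: SpectralDataset,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
) -> SplitPlan:
    """Allocate each class's bottles by fixed fractions (largest-remainder rounding)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    allocs = []
    for k in dataset.class_ids:
        n = len(set(dataset.meta.loc[dataset.class_labels == k, "bottle_id"]))
        raw = np.asarray(fractions) * n
        counts = np.floor(raw).astype(int)
        for _ in range(n - counts.sum()):
            counts[int(np.argmax(raw - counts))] += 1
        if counts[0] < 2:
            raise ConfigError(f"class {k}: fewer than 2 calibration bottles ({counts[0]})")
        allocs.append(GroupAllocation(int(k), *map(int, counts)))
    return SplitPlan(tuple(allocs), seed=seed)
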