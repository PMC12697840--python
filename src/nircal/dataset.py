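"""Spectral dataset container and plain-text I/O.

A :class:`SpectralDataset` bundles everything one calibration experiment
needs: the instrument grid (wavenumbers in cm^-1 or wavelengths in nm), a
samples x points absorbance matrix in log(1/R) units, a per-sample table of
reference component values (%, dry basis) and a role tag per sample
(``synthetic`` standards, ``calibration``, ``validation`` or
``unassigned``).

Spectra are exchanged as wide CSV: the header row carries the literal grid
values, the first column the sample id, one row per scan.  Repeated ids are
replicate scans and are averaged point-wise at read time, mirroring the
usual FT-NIR practice of scanning each cup twice and using the mean
spectrum.  Reference values travel in a sidecar CSV keyed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "read_spectra",
    "read_components",
    "write_spectra",
    "write_components",
    "resample_to_grid",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
]

ROLES = ("synthetic", "calibration", "validation", "unassigned")


def nm_to_wavenumber(nm):
    """Convert wavelength in nm to wavenumber in cm^-1 (1e7 / lambda)."""
    return 1e7 / np.asarray(nm, dtype=float)


def wavenumber_to_nm(wn):
    """Convert wavenumber in cm^-1 to wavelength in nm."""
    return 1e7 / np.asarray(wn, dtype=float)


@dataclass
class SpectralDataset:
    """In-memory spectral dataset.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per absorbance row.
    grid : ndarray, shape (n_points,)
        Strictly monotone axis values.
    absorbance : ndarray, shape (n_samples, n_points)
        log(1/R) absorbance.
    components : DataFrame or None
        Reference values per sample (%, dry basis), indexed by sample id;
        may be missing entirely or hold NaN for unmeasured samples.
    axis_unit : {"cm-1", "nm"}
    roles : ndarray of str, optional
        Per-sample role tag; defaults to ``unassigned``.
    """

    sample_ids: list
    grid: np.ndarray
    absorbance: np.ndarray
    components: pd.DataFrame | None = None
    axis_unit: str = "cm-1"
    roles: np.ndarray = field(default=None)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x points)")
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} absorbance rows"
            )
        if p != self.grid.size:
            raise ValueError(f"{self.grid.size} grid points but {p} absorbance columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        d = np.diff(self.grid)
        if self.grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("grid must be strictly monotone")
        if self.axis_unit not in ("cm-1", "nm"):
            raise ValueError(f"unknown axis unit {self.axis_unit!r}")
        if self.roles is None:
            self.roles = np.array(["unassigned"] * n, dtype=object)
        else:
            self.roles = np.asarray(self.roles, dtype=object)
            if self.roles.size != n:
                raise ValueError("one role per sample required")
            bad = set(self.roles) - set(ROLES)
            if bad:
                raise ValueError(f"unknown roles: {sorted(bad)}")
        if self.components is not None:
            vals = self.components.to_numpy(dtype=float)
            finite_or_nan = np.isnan(vals) | np.isfinite(vals)
            if not finite_or_nan.all():
                raise ValueError("component values must be finite where present")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def component_values(self, name: str) -> np.ndarray:
        """Reference values of one component, aligned to sample order."""
        if self.components is None or name not in self.components.columns:
            raise KeyError(f"component {name!r} not available")
        return self.components.reindex(self.sample_ids)[name].to_numpy(dtype=float)

    def subset(self, indices) -> "SpectralDataset":
        """New dataset restricted to ``indices`` (order preserved)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        ids = [self.sample_ids[i] for i in indices]
        comp = None
        if self.components is not None:
            comp = self.components.reindex(ids)
        return SpectralDataset(
            sample_ids=ids,
            grid=self.grid.copy(),
            absorbance=self.absorbance[indices],
            components=comp,
            axis_unit=self.axis_unit,
            roles=self.roles[indices].copy(),
        )

    def with_role(self, role: str) -> "SpectralDataset":
        """Subset of samples carrying ``role``."""
        return self.subset(self.roles == role)

    def assign_role(self, role: str, indices=None) -> "SpectralDataset":
        """Copy with ``role`` assigned to ``indices`` (all samples if None)."""
        roles = self.roles.copy()
        if indices is None:
            roles[:] = role
        else:
            roles[np.asarray(indices)] = role
        return replace(self, roles=roles)

    def shuffled(self, seed: int) -> "SpectralDataset":
        """Copy with sample order permuted by a seeded RNG."""
        rng = np.random.default_rng(seed)
        return self.subset(rng.permutation(self.n_samples))


# ----------------------------------------------------------------------
# I/O


def read_spectra(path, components_path=None) -> SpectralDataset:
    """Read a wide-CSV spectra file (header = grid, first column = id).

    Rows sharing an id are replicate scans and are averaged point-wise.
    ``components_path`` optionally attaches a reference-value CSV keyed by
    sample id.
    """
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(header) < 2:
        raise ValueError("spectra file needs an id column plus grid columns")
    try:
        grid = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric grid value in header: {exc}") from None
    if np.unique(grid).size != grid.size:
        raise ValueError("duplicate grid values in header")
    df = pd.read_csv(path, skiprows=1, header=None, dtype={0: str})
    if df.shape[1] != len(header):
        raise ValueError("ragged rows: column count differs from header")
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("ragged or non-numeric spectrum rows")
    ids_col = df.iloc[:, 0].astype(str)
    # replicate averaging, first-appearance order
    order = ids_col.drop_duplicates().tolist()
    groups = {sid: [] for sid in order}
    for sid, row in zip(ids_col, mat):
        groups[sid].append(row)
    averaged = np.vstack([np.mean(groups[sid], axis=0) for sid in order])
    comp = read_components(components_path) if components_path else None
    unit = "cm-1" if grid.max() > 3000 else "nm"
    return SpectralDataset(order, grid, averaged, components=comp, axis_unit=unit)


def read_components(path) -> pd.DataFrame:
    """Read a component-reference CSV ('id' column plus one column per trait)."""
    df = pd.read_csv(path, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "id"
    return df.astype(float)


def write_spectra(ds: SpectralDataset, path, fmt: str = "%.8g") -> None:
    """Write the wide-CSV spectra representation of ``ds``."""
    df = pd.DataFrame(ds.absorbance, columns=[fmt % g for g in ds.grid])
    df.insert(0, "id", ds.sample_ids)
    df.to_csv(path, index=False, float_format=fmt)


def write_components(ds: SpectralDataset, path, fmt: str = "%.8g") -> None:
    if ds.components is None:
        raise ValueError("dataset carries no component table")
    ds.components.to_csv(path, float_format=fmt, index_label="id")


# ----------------------------------------------------------------------


def resample_to_grid(ds: SpectralDataset, target_grid) -> SpectralDataset:
    """Linearly interpolate every spectrum onto ``target_grid``.

    The target grid must lie inside the source grid's closed range: this is
    a resampling bridge for cross-instrument use, not an extrapolator.
    """
    target = np.asarray(target_grid, dtype=float)
    d = np.diff(target)
    if target.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("target grid must be strictly monotone")
    lo, hi = ds.grid.min(), ds.grid.max()
    if target.min() < lo or target.max() > hi:
        raise ValueError(
            f"target grid [{target.min()}, {target.max()}] outside source "
            f"range [{lo}, {hi}]; extrapolation refused"
        )
    # np.interp needs ascending abscissae
    src = ds.grid
    mat = ds.absorbance
    if src.size > 1 and src[1] < src[0]:
        src = src[::-1]
        mat = mat[:, ::-1]
    out = np.vstack([np.interp(target, src, row) for row in mat])
    return replace(ds, grid=target, absorbance=out)
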