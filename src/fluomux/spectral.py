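"""Spectral measurement space and parametric fluorophore fingerprints.

A multiplexed spectral acquisition excites the field of view sequentially with
six laser lines and records the emission in 34 wavelength bins, giving a
204-dimensional *spectral fingerprint* per fluorophore or per ROI.  This module
defines the grid (lasers x bins), a parametric Gaussian excitation/emission
model used to synthesise fingerprints, and the reference library consumed by
the linear unmixer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LASERS",
    "SpectralGrid",
    "SpectrumModel",
    "Fingerprint",
    "ReferenceLibrary",
    "build_grid",
    "fingerprint_from_model",
    "normalize_fingerprint",
    "DEFAULT_SPECTRA",
    "default_library",
    "fingerprints_to_frame",
    "frame_to_fingerprints",
    "write_fingerprint_table",
    "read_fingerprint_table",
]

#: Default excitation laser lines (nm).
DEFAULT_LASERS: tuple[float, ...] = (405.0, 488.0, 514.0, 561.0, 594.0, 639.0)

#: Guard band half-width (nm) around each laser line where emission bins are
#: blanked, emulating beam-splitter rejection of scattered excitation light.
LASER_BLOCK_NM = 10.0


class ConfigurationError(ValueError):
    """Raised when a grid or model specification is inconsistent."""


@dataclass(frozen=True)
class SpectralGrid:
    """The laser x emission-bin measurement space.

    The default grid has 6 lasers and 34 bins: one wide multialkali bin at
    350-400 nm, 32 uniform ~9.22 nm bins partitioning 400-695 nm, and one wide
    bin at 695-750 nm - 204 channels in total.
    """

    laser_wavelengths: tuple[float, ...]
    bin_edges: tuple[float, ...]

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ConfigurationError("bin_edges must hold at least two values")
        if not np.all(np.diff(edges) > 0):
            raise ConfigurationError("bin edges must be strictly increasing")
        if len(self.laser_wavelengths) == 0:
            raise ConfigurationError("at least one laser is required")

    @property
    def n_lasers(self) -> int:
        return len(self.laser_wavelengths)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def n_channels(self) -> int:
        return self.n_lasers * self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges)
        return 0.5 * (edges[:-1] + edges[1:])

    def bin_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.asarray(self.bin_edges)
        return edges[:-1], edges[1:]


def build_grid(
    laser_wavelengths=DEFAULT_LASERS,
    interior_span: tuple[float, float] = (400.0, 695.0),
    n_interior: int = 32,
    end_spans: tuple[float, float] = (350.0, 750.0),
) -> SpectralGrid:
    """Build the spectral grid: two wide end bins flanking uniform interior bins.

    Defaults reproduce the 6-laser x 34-bin (204 channel) acquisition space:
    interior bins of (695-400)/32 ~ 9.22 nm plus 350-400 and 695-750 nm end
    bins.
    """
    lo, hi = interior_span
    if not (end_spans[0] < lo < hi < end_spans[1]):
        raise ConfigurationError("end spans must bracket the interior span")
    if n_interior < 1:
        raise ConfigurationError("n_interior must be >= 1")
    interior = np.linspace(lo, hi, n_interior + 1)
    edges = np.concatenate(([end_spans[0]], interior, [end_spans[1]]))
    return SpectralGrid(tuple(float(w) for w in laser_wavelengths), tuple(edges))


@dataclass(frozen=True)
class SpectrumModel:
    """Parametric fluorophore: unit-peak Gaussian excitation and emission curves.

    Parameters are the excitation/emission peak wavelengths and Gaussian widths
    (standard deviations, nm) plus a relative brightness.  The Stokes shift must
    be non-negative (``em_peak >= ex_peak``).
    """

    name: str
    ex_peak: float
    em_peak: float
    ex_width: float = 18.0
    em_width: float = 22.0
    brightness: float = 1.0

    def __post_init__(self):
        if self.em_peak < self.ex_peak:
            raise ConfigurationError(
                f"{self.name}: emission peak {self.em_peak} below excitation "
                f"peak {self.ex_peak} (negative Stokes shift)"
            )
        if self.ex_width <= 0 or self.em_width <= 0:
            raise ConfigurationError(f"{self.name}: widths must be positive")
        if self.brightness < 0:
            raise ConfigurationError(f"{self.name}: brightness must be >= 0")

    def excitation(self, wavelengths) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        return np.exp(-0.5 * ((lam - self.ex_peak) / self.ex_width) ** 2)

    def emission(self, wavelengths) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        return np.exp(-0.5 * ((lam - self.em_peak) / self.em_width) ** 2)


@dataclass
class Fingerprint:
    """Nonnegative (laser, bin) intensity matrix for one fluorophore or ROI."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("fingerprint values must be a (laser, bin) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("fingerprint contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flatten(self) -> np.ndarray:
        """Row-major 1-D view: laser-major, bin-minor (204 on the default grid)."""
        return self.values.ravel()

    def max(self) -> float:
        return float(self.values.max())


def normalize_fingerprint(f: Fingerprint, mode: str = "max_one") -> Fingerprint:
    """Rescale a fingerprint to unit maximum (``max_one``) or unit sum (``unit_sum``)."""
    total = f.values.sum()
    peak = f.values.max()
    if mode == "max_one":
        if peak <= 0:
            raise ValueError("cannot max-normalize an all-zero fingerprint")
        return Fingerprint(f.values / peak, f.label)
    if mode == "unit_sum":
        if total <= 0:
            raise ValueError("cannot sum-normalize an all-zero fingerprint")
        return Fingerprint(f.values / total, f.label)
    raise ValueError(f"unknown normalization mode {mode!r}")


_SQRT2 = math.sqrt(2.0)


def _gaussian_bin_integral(peak: float, width: float, lo, hi) -> np.ndarray:
    # integral of the unit-peak Gaussian over [lo, hi]; closed form via erf
    from scipy.special import erf

    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    scale = width * math.sqrt(math.pi / 2.0)
    a = (lo - peak) / (width * _SQRT2)
    b = (hi - peak) / (width * _SQRT2)
    return scale * (erf(b) - erf(a))


def fingerprint_from_model(
    model: SpectrumModel,
    grid: SpectralGrid,
    laser_powers=None,
    transmission=None,
    block_nm: float = LASER_BLOCK_NM,
) -> Fingerprint:
    """Sample a parametric fluorophore onto the (laser, bin) grid.

    Entry (l, b) = brightness * power_l * T(lambda_l) * Ex(lambda_l) *
    integral of the emission curve over bin b.  Bins overlapping the guard band
    ``[lambda_l - block_nm, lambda_l + block_nm]`` are zeroed, emulating
    rejection of the excitation line.  ``transmission`` is an optional
    wavelength -> fraction callable (defaults to 1 everywhere).
    """
    lasers = np.asarray(grid.laser_wavelengths, dtype=float)
    if laser_powers is None:
        powers = np.ones(grid.n_lasers)
    else:
        powers = np.asarray(laser_powers, dtype=float)
        if powers.shape != (grid.n_lasers,):
            raise ConfigurationError("laser_powers length must match grid lasers")
        if np.any(powers < 0):
            raise ConfigurationError("laser powers must be >= 0")
    trans = np.ones(grid.n_lasers) if transmission is None else np.asarray(
        [float(transmission(l)) for l in lasers]
    )
    lo, hi = grid.bin_bounds()
    em = _gaussian_bin_integral(model.em_peak, model.em_width, lo, hi)
    ex = model.excitation(lasers)
    vals = model.brightness * (powers * trans * ex)[:, None] * em[None, :]
    # blank bins that overlap the guard band around each laser line
    blocked = (lo[None, :] < lasers[:, None] + block_nm) & (
        hi[None, :] > lasers[:, None] - block_nm
    )
    vals = np.where(blocked, 0.0, vals)
    return Fingerprint(np.clip(vals, 0.0, None), model.name)


#: Default fluorophore set: the nine retrograde labels plus the calcium
#: indicator GCaMP6s, with approximate published excitation/emission peaks (nm).
DEFAULT_SPECTRA: tuple[SpectrumModel, ...] = (
    SpectrumModel("mTagBFP2", 399, 454),
    SpectrumModel("mTurquoise2", 434, 474),
    SpectrumModel("T-Sapphire", 399, 511),
    SpectrumModel("GCaMP6s", 497, 515),
    SpectrumModel("mVenus", 515, 528),
    SpectrumModel("mOrange2", 549, 565),
    SpectrumModel("mCyRFP1", 528, 594),
    SpectrumModel("mScarlet", 569, 594),
    SpectrumModel("FusionRed", 580, 608),
    SpectrumModel("mNeptune2.5", 599, 643),
)

GCAMP = "GCaMP6s"


@dataclass
class ReferenceLibrary:
    """Ordered collection of reference fingerprints sharing one grid.

    The flattened fingerprints form the design matrix of the linear unmixer;
    the library checks that they are numerically full rank and exposes the
    condition number.
    """

    fingerprints: list[Fingerprint]
    grid: SpectralGrid

    def __post_init__(self):
        shapes = {f.shape for f in self.fingerprints}
        expected = (self.grid.n_lasers, self.grid.n_bins)
        if shapes and shapes != {expected}:
            raise ValueError(f"fingerprint shapes {shapes} do not match grid {expected}")
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate fluorophore labels in library")

    @property
    def names(self) -> list[str]:
        return [f.label for f in self.fingerprints]

    def __len__(self) -> int:
        return len(self.fingerprints)

    def __getitem__(self, name: str) -> Fingerprint:
        for f in self.fingerprints:
            if f.label == name:
                return f
        raise KeyError(name)

    def matrix(self) -> np.ndarray:
        """(n_channels, n_fluorophores) design matrix of flattened fingerprints."""
        return np.stack([f.flatten() for f in self.fingerprints], axis=1)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix()))

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix()))

    def is_full_rank(self) -> bool:
        return self.rank() == len(self)

    def subset(self, names) -> "ReferenceLibrary":
        return ReferenceLibrary([self[n] for n in names], self.grid)

    def normalized(self, mode: str = "max_one") -> "ReferenceLibrary":
        return ReferenceLibrary(
            [normalize_fingerprint(f, mode) for f in self.fingerprints], self.grid
        )


def default_library(
    grid: SpectralGrid | None = None,
    names=None,
    brightness: dict[str, float] | None = None,
    normalize: bool = True,
) -> ReferenceLibrary:
    """Build the default 10-fluorophore reference library on ``grid``.

    ``brightness`` overrides relative brightness per fluorophore (emulating dim
    reporters).  With ``normalize`` the fingerprints are scaled to unit peak so
    that simulated amplitudes are directly peak signal levels.
    """
    grid = grid or build_grid()
    models = list(DEFAULT_SPECTRA)
    if names is not None:
        lookup = {m.name: m for m in models}
        models = [lookup[n] for n in names]
    if brightness:
        models = [
            replace(m, brightness=brightness.get(m.name, m.brightness)) for m in models
        ]
    fps = [fingerprint_from_model(m, grid) for m in models]
    if normalize:
        fps = [
            Fingerprint(f.values * (m.brightness / f.values.max()), f.label)
            for f, m in zip(fps, models)
        ]
    return ReferenceLibrary(fps, grid)


# ---------------------------------------------------------------------------
# delimited-text I/O


def fingerprints_to_frame(fps, grid: SpectralGrid) -> pd.DataFrame:
    """Long-form table: one row per (label, laser, bin) with bin bounds in nm."""
    lo, hi = grid.bin_bounds()
    rows = []
    for f in fps:
        for i, laser in enumerate(grid.laser_wavelengths):
            for j in range(grid.n_bins):
                rows.append(
                    (f.label, laser, float(lo[j]), float(hi[j]), f.values[i, j])
                )
    return pd.DataFrame(
        rows, columns=["label", "laser_nm", "bin_lo_nm", "bin_hi_nm", "value"]
    )


def frame_to_fingerprints(df: pd.DataFrame) -> tuple[list[Fingerprint], SpectralGrid]:
    lasers = tuple(sorted(df["laser_nm"].unique()))
    lows = np.sort(df["bin_lo_nm"].unique())
    highs = np.sort(df["bin_hi_nm"].unique())
    edges = tuple(np.append(lows, highs[-1]))
    grid = SpectralGrid(lasers, edges)
    laser_ix = {l: i for i, l in enumerate(lasers)}
    bin_ix = {lo: j for j, lo in enumerate(lows)}
    fps = []
    for label, sub in df.groupby("label", sort=False):
        vals = np.zeros((grid.n_lasers, grid.n_bins))
        vals[
            [laser_ix[l] for l in sub["laser_nm"]],
            [bin_ix[b] for b in sub["bin_lo_nm"]],
        ] = sub["value"].to_numpy()
        fps.append(Fingerprint(vals, str(label)))
    return fps, grid


def write_fingerprint_table(path, fps, grid: SpectralGrid) -> None:
    fingerprints_to_frame(fps, grid).to_csv(path, index=False)


def read_fingerprint_table(path) -> ReferenceLibrary:
    fps, grid = frame_to_fingerprints(pd.read_csv(path))
    return ReferenceLibrary(fps, grid)
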