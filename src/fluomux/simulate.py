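"""Monte-Carlo simulation of ROI spectral datasets and image fixtures.

Synthetic single- and dual-label ROI fingerprints are drawn from the reference
library with the perturbations used to characterise the classifier: calcium-
indicator (GCaMP) background, uniform spectral background, additive white
noise at a stated SNR, and skewed class distributions.  A paired confocal/
miniscope image generator provides an end-to-end fixture with known ground
truth for the full registration + extraction + unmixing pipeline.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .register import SimilarityTransform, apply_transform
from .spectral import (
    GCAMP,
    Fingerprint,
    ReferenceLibrary,
    SpectrumModel,
    default_library,
    fingerprint_from_model,
)
from .stacks import ROIMask, SpectralStack
from .unmix import AssignmentResult, classify_subject

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Metrics",
    "EMPIRICAL_DISTRIBUTION",
    "FOUR_FLUOR_DISTRIBUTION",
    "equal_distribution_config",
    "prevalence_config",
    "realistic_config",
    "dual_label_config",
    "noise_sd",
    "simulate_roi_dataset",
    "evaluate_assignments",
    "run_sweep",
    "simulate_vessel_image",
    "simulate_image_pair",
]

#: Empirical-like in vivo class distribution over the nine injected
#: fluorophores (bright, densely projecting labels detected most often).
EMPIRICAL_DISTRIBUTION: dict[str, float] = {
    "T-Sapphire": 0.20,
    "mVenus": 0.20,
    "mOrange2": 0.12,
    "mScarlet": 0.10,
    "mTagBFP2": 0.09,
    "mTurquoise2": 0.09,
    "mNeptune2.5": 0.09,
    "FusionRed": 0.06,
    "mCyRFP1": 0.05,
}

#: Empirical-like distribution for the reduced four-fluorophore paradigm.
FOUR_FLUOR_DISTRIBUTION: dict[str, float] = {
    "mVenus": 0.35,
    "mOrange2": 0.30,
    "mNeptune2.5": 0.20,
    "mTagBFP2": 0.15,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated ROI dataset.

    ``gcamp_fraction`` (g) and ``background_fraction`` (b) scale the added
    GCaMP spectrum and uniform fluorophore mixture relative to the mean
    fluorophore amplitude; ``snr`` is mean peak signal over noise SD
    (``inf`` = noiseless); amplitudes are log-normal with ``amplitude_sigma``
    log-SD around a unit median.
    """

    class_distribution: dict[str, float]
    n_rois: int = 460
    gcamp_fraction: float = 0.0
    background_fraction: float = 0.0
    snr: float = math.inf
    dual_label: bool = False
    replicates: int = 100
    seed: int = 0
    amplitude_sigma: float = 0.5
    second_fluor_background: bool = False

    def __post_init__(self):
        fracs = np.array(list(self.class_distribution.values()))
        if np.any(fracs < 0) or not math.isclose(fracs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class fractions must be >= 0 and sum to 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")


def equal_distribution_config(
    names, n_rois: int = 460, snr: float = 20.0, seed: int = 0, **kw
) -> SimulationConfig:
    """Equal class fractions over ``names`` at low noise."""
    names = list(names)
    dist = {n: 1.0 / len(names) for n in names}
    return SimulationConfig(dist, n_rois=n_rois, snr=snr, seed=seed, **kw)


def prevalence_config(
    names, dominant: str, prevalence: float, n_rois: int = 460,
    snr: float = 20.0, seed: int = 0, **kw,
) -> SimulationConfig:
    """One fluorophore at ``prevalence``; the rest share the remainder equally."""
    others = [n for n in names if n != dominant]
    dist = {n: (1.0 - prevalence) / len(others) for n in others}
    dist[dominant] = prevalence
    return SimulationConfig(dist, n_rois=n_rois, snr=snr, seed=seed, **kw)


def realistic_config(
    distribution: dict[str, float] | None = None,
    n_rois: int = 460,
    seed: int = 0,
    **kw,
) -> SimulationConfig:
    """The realistic-condition preset: empirical-like distribution, g = 0.30,
    b = 0.30, SNR = 6."""
    dist = dict(distribution or EMPIRICAL_DISTRIBUTION)
    return SimulationConfig(
        dist,
        n_rois=n_rois,
        gcamp_fraction=0.30,
        background_fraction=0.30,
        snr=6.0,
        seed=seed,
        **kw,
    )


def dual_label_config(
    names, n_per_group: int = 5, snr: float = math.inf, seed: int = 0, **kw
) -> SimulationConfig:
    """All pairwise fluorophore combinations plus single-label controls.

    The roster holds ``n_per_group`` ROIs for every unordered pair and for
    every single fluorophore; ``n_rois`` is derived from the roster size.
    """
    names = list(names)
    n_pairs = len(names) * (len(names) - 1) // 2
    n_rois = n_per_group * (n_pairs + len(names))
    dist = {n: 1.0 / len(names) for n in names}
    return SimulationConfig(
        dist, n_rois=n_rois, snr=snr, dual_label=True, seed=seed, **kw
    )


@dataclass
class GroundTruth:
    """Known identity of every simulated ROI."""

    roi_ids: list[str]
    labels: list[tuple[str, ...]]  # 1 name (single) or 2 names (dual)
    amplitudes: list[tuple[float, ...]]
    perturbation: dict = field(default_factory=dict)

    def __post_init__(self):
        for lab in self.labels:
            if len(lab) == 2 and lab[0] == lab[1]:
                raise ValueError("dual-label ROI must list two distinct fluorophores")

    def is_dual(self, i: int) -> bool:
        return len(self.labels[i]) == 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "labels": [";".join(l) for l in self.labels],
                "amplitudes": [";".join(f"{a:.6g}" for a in t) for t in self.amplitudes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        return cls(
            [str(r) for r in df["roi_id"]],
            [tuple(str(l).split(";")) for l in df["labels"]],
            [tuple(float(x) for x in str(a).split(";")) for a in df["amplitudes"]],
        )


def noise_sd(mean_amplitude: float, snr: float) -> float:
    """SNR definition: mean peak spectral amplitude divided by noise SD."""
    return 0.0 if math.isinf(snr) else mean_amplitude / snr


def _draw_labels(config: SimulationConfig, rng: np.random.Generator):
    names = list(config.class_distribution)
    fracs = np.array([config.class_distribution[n] for n in names])
    if config.dual_label:
        pairs = list(itertools.combinations(names, 2))
        groups = pairs + [(n,) for n in names]
        reps = max(1, config.n_rois // len(groups))
        roster = [g for g in groups for _ in range(reps)]
        return roster
    idx = rng.choice(len(names), size=config.n_rois, p=fracs / fracs.sum())
    return [(names[i],) for i in idx]


def simulate_roi_dataset(
    config: SimulationConfig,
    library: ReferenceLibrary,
    rng: np.random.Generator | None = None,
) -> tuple[list[Fingerprint], GroundTruth]:
    """Draw a synthetic ROI fingerprint dataset with its ground truth.

    Each ROI is amplitude x reference (two summed references for dual-label
    ROIs), plus g*A_mean x GCaMP, plus b*A_mean x the uniform mixture of the
    non-GCaMP references, plus white noise with SD = A_mean / snr, clipped at
    zero.  With ``second_fluor_background`` the mixture is replaced by a
    randomly chosen second fluorophore scaled to b x the ROI's own amplitude
    (the spatial-overlap model).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.gcamp_fraction > 0 and GCAMP not in library.names:
        raise ValueError("GCaMP reference required for gcamp_fraction > 0")
    missing = set(config.class_distribution) - set(library.names)
    if missing:
        raise ValueError(f"class distribution names not in library: {sorted(missing)}")
    ref = {n: library[n].values for n in library.names}
    non_gcamp = [n for n in library.names if n != GCAMP]
    mixture = np.mean([ref[n] for n in non_gcamp], axis=0)
    labels = _draw_labels(config, rng)
    n = len(labels)
    amps = np.exp(rng.normal(0.0, config.amplitude_sigma, size=(n, 2)))
    mean_amp = float(amps[:, 0].mean())
    sd = noise_sd(mean_amp, config.snr)
    spectra, truths_amp = [], []
    for i, lab in enumerate(labels):
        vals = amps[i, 0] * ref[lab[0]]
        roi_amps = (float(amps[i, 0]),)
        if len(lab) == 2:
            vals = vals + amps[i, 1] * ref[lab[1]]
            roi_amps = (float(amps[i, 0]), float(amps[i, 1]))
        if config.gcamp_fraction > 0:
            vals = vals + config.gcamp_fraction * mean_amp * ref[GCAMP]
        if config.background_fraction > 0:
            if config.second_fluor_background:
                # spatial-overlap model: a second cell's spectrum scaled
                # relative to this ROI's own amplitude
                choices = [c for c in non_gcamp if c not in lab]
                other = choices[rng.integers(len(choices))]
                vals = vals + config.background_fraction * amps[i, 0] * ref[other]
            else:
                vals = vals + config.background_fraction * mean_amp * mixture
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=vals.shape)
        spectra.append(Fingerprint(np.clip(vals, 0.0, None), f"roi{i:04d}"))
        truths_amp.append(roi_amps)
    truth = GroundTruth(
        [s.label for s in spectra],
        list(labels),
        truths_amp,
        perturbation={
            "gcamp_fraction": config.gcamp_fraction,
            "background_fraction": config.background_fraction,
            "snr": config.snr,
            "second_fluor_background": config.second_fluor_background,
            "mean_amplitude": mean_amp,
        },
    )
    return spectra, truth


@dataclass
class Metrics:
    """Classification performance against ground truth.

    Single-label ROIs: ``accuracy`` (correct primary) + ``false_negative_rate``
    (no match) + ``false_positive_rate`` (incorrect match) = 1.  Dual-label
    ROIs are scored by whether the identity set contains at least one / both of
    the true pair, and whether it contains any fluorophore outside the pair.
    """

    n_single: int
    n_dual: int
    accuracy: float
    false_negative_rate: float
    false_positive_rate: float
    dual_at_least_one: float = float("nan")
    dual_both: float = float("nan")
    dual_secondary_fp: float = float("nan")
    per_fluorophore: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "n_single": self.n_single,
            "n_dual": self.n_dual,
            "accuracy": self.accuracy,
            "false_negative_rate": self.false_negative_rate,
            "false_positive_rate": self.false_positive_rate,
            "dual_at_least_one": self.dual_at_least_one,
            "dual_both": self.dual_both,
            "dual_secondary_fp": self.dual_secondary_fp,
        }
        for name, stats in self.per_fluorophore.items():
            row[f"acc_{name}"] = stats["accuracy"]
        return row


def evaluate_assignments(
    results: list[AssignmentResult], truth: GroundTruth
) -> Metrics:
    """Score assignments against known identities."""
    by_id = {a.roi_id: a for a in results}
    if set(by_id) != set(truth.roi_ids):
        raise ValueError("assignment and ground-truth roi_ids do not match")
    n_single = n_dual = 0
    correct = fn = fp = 0
    dual_one = dual_both = dual_fp = 0
    per: dict[str, dict[str, float]] = {}
    for i, roi in enumerate(truth.roi_ids):
        a = by_id[roi]
        lab = truth.labels[i]
        if len(lab) == 1:
            n_single += 1
            stats = per.setdefault(lab[0], {"n": 0, "correct": 0, "fn": 0, "fp": 0})
            stats["n"] += 1
            if a.primary is None:
                fn += 1
                stats["fn"] += 1
            elif a.primary == lab[0]:
                correct += 1
                stats["correct"] += 1
            else:
                fp += 1
                stats["fp"] += 1
        else:
            n_dual += 1
            ids = a.identities()
            pair = set(lab)
            if ids & pair:
                dual_one += 1
            if pair <= ids:
                dual_both += 1
            if ids - pair:
                dual_fp += 1
    per_fluor = {
        name: {
            "n": s["n"],
            "accuracy": s["correct"] / s["n"],
            "false_negative_rate": s["fn"] / s["n"],
            "false_positive_rate": s["fp"] / s["n"],
        }
        for name, s in per.items()
    }
    return Metrics(
        n_single=n_single,
        n_dual=n_dual,
        accuracy=correct / n_single if n_single else float("nan"),
        false_negative_rate=fn / n_single if n_single else float("nan"),
        false_positive_rate=fp / n_single if n_single else float("nan"),
        dual_at_least_one=dual_one / n_dual if n_dual else float("nan"),
        dual_both=dual_both / n_dual if n_dual else float("nan"),
        dual_secondary_fp=dual_fp / n_dual if n_dual else float("nan"),
        per_fluorophore=per_fluor,
    )


def _vary(config: SimulationConfig, axis: str, value: float) -> SimulationConfig:
    if axis == "gcamp":
        return replace(config, gcamp_fraction=value)
    if axis == "background":
        return replace(config, background_fraction=value)
    if axis == "snr":
        return replace(config, snr=value)
    if axis == "prevalence":
        dominant = max(config.class_distribution, key=config.class_distribution.get)
        return prevalence_config(
            list(config.class_distribution),
            dominant,
            value,
            n_rois=config.n_rois,
            snr=config.snr,
            seed=config.seed,
            gcamp_fraction=config.gcamp_fraction,
            background_fraction=config.background_fraction,
            amplitude_sigma=config.amplitude_sigma,
        )
    raise ValueError(f"unknown sweep axis {axis!r}")


def run_sweep(
    base: SimulationConfig,
    axis: str,
    values,
    library: ReferenceLibrary,
    classifier_options: dict | None = None,
    replicates: int | None = None,
) -> pd.DataFrame:
    """Simulate -> classify -> evaluate for every value x replicate.

    Returns one tidy row per (value, replicate) with overall and
    per-fluorophore metrics; replicate random streams are spawned from the
    config seed so results are reproducible and independent of sweep order.
    """
    opts = dict(classifier_options or {})
    reps = replicates if replicates is not None else base.replicates
    rows = []
    for value in values:
        cfg = _vary(base, axis, value)
        streams = np.random.SeedSequence([base.seed, int(round(1e6 * value))]).spawn(reps)
        for r, stream in enumerate(streams):
            rng = np.random.default_rng(stream)
            spectra, truth = simulate_roi_dataset(cfg, library, rng=rng)
            res = classify_subject(spectra, library, **opts)
            m = evaluate_assignments(res.assignments, truth)
            row = {"axis": axis, "value": value, "replicate": r}
            row.update(m.as_row())
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired image fixture


def simulate_vessel_image(
    shape: tuple[int, int],
    rng: np.random.Generator,
    n_vessels: int = 12,
    vessel_depth: float = 0.7,
) -> np.ndarray:
    """Bright field with dark random-walk vessel trees (values in [0, 1])."""
    h, w = shape
    mask = np.zeros(shape)
    for _ in range(n_vessels):
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(int(2.0 * max(h, w))):
            angle += rng.normal(0, 0.25)
            r += np.sin(angle)
            c += np.cos(angle)
            if not (0 <= r < h and 0 <= c < w):
                break
            rr, cc = int(round(r)), int(round(c))
            mask[max(0, rr - 1) : rr + 2, max(0, cc - 1) : cc + 2] = 1.0
    vessels = ndimage.gaussian_filter(mask, 1.0)
    vessels = vessels / vessels.max() if vessels.max() > 0 else vessels
    return np.clip(1.0 - vessel_depth * vessels, 0.0, 1.0)


def simulate_vessel_pair(
    seed: int,
    transform: SimilarityTransform,
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.05,
    pad: int = 32,
    n_vessels: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed/moving vessel image pair related by a known similarity transform.

    A larger world is rendered and both views are centre-cropped from it, so
    the moving frame carries genuine image content everywhere (no constant
    border).  ``noise_sd`` is additive white noise on unit-range images
    (0.05 ~ SNR 10 relative to the mean vessel contrast, ~0.5).
    """
    rng = np.random.default_rng(seed)
    big = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    world = simulate_vessel_image(big, rng, n_vessels=n_vessels)
    moving_big = apply_transform(world, transform.inverse(), cval=1.0)
    sl = (slice(pad, pad + shape[0]), slice(pad, pad + shape[1]))
    fixed = world[sl] + rng.normal(0, noise_sd, shape)
    moving = moving_big[sl] + rng.normal(0, noise_sd, shape)
    return fixed, moving


def _place_cells(
    shape, n_cells, rng, margin: float, min_sep: float, max_tries: int = 2000
):
    h, w = shape
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < n_cells and tries < max_tries:
        tries += 1
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centres):
            centres.append((r, c))
    if len(centres) < n_cells:
        warnings.warn(
            f"could only place {len(centres)}/{n_cells} somata at the density cap"
        )
    return centres


def simulate_image_pair(
    seed: int,
    library: ReferenceLibrary,
    transform: SimilarityTransform,
    shape: tuple[int, int] = (96, 96),
    n_cells: int = 24,
    cell_radius: float = 3.0,
    snr: float = 10.0,
    n_z: int = 2,
    pixel_size: float = 2.0,
    background_level: float = 0.5,
):
    """Render a matched confocal spectral-stack / miniscope image pair.

    The scene lives in confocal coordinates: dark vessels on a bright field
    with disk somata carrying per-class fingerprints.  Confocal stacks are
    rendered per (laser, bin) with the class fingerprints plus a spectrally
    broad vessel background and white noise; the miniscope image is the
    inverse-transformed GCaMP-like intensity image (cells + dark vessels),
    blurred and noised.  ROI masks are produced in miniscope coordinates.

    Returns ``(stacks, miniscope_image, masks, truth, reference_image)`` where
    ``stacks`` maps laser -> :class:`SpectralStack` and ``reference_image`` is
    the vessel-contrast confocal channel used for registration.
    """
    rng = np.random.default_rng(seed)
    grid = library.grid
    names = [n for n in library.names if n != GCAMP]
    # render the world on a padded canvas so the inverse-warped miniscope view
    # is filled with genuine content (no empty border ring); both views are
    # centred crops, so the similarity transform about the crop centre holds
    half = shape[0] / 2.0
    reach = transform.scale * half * math.sqrt(2.0)
    reach += max(abs(transform.tx), abs(transform.ty))
    pad = int(math.ceil(max(0.0, reach - half))) + 4
    big = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    crop = (slice(pad, pad + shape[0]), slice(pad, pad + shape[1]))
    vessel_big = simulate_vessel_image(big, rng, n_vessels=16)
    vessel_world = vessel_big[crop]
    margin = pad + cell_radius + 4
    centres_big = _place_cells(big, n_cells, rng, margin, min_sep=3.0 * cell_radius)
    classes = [names[rng.integers(len(names))] for _ in centres_big]
    amps = np.exp(rng.normal(0.0, 0.3, size=len(centres_big)))
    byy, bxx = np.mgrid[0 : big[0], 0 : big[1]]
    cell_maps_big = [
        amp * ((byy - r) ** 2 + (bxx - c) ** 2 <= cell_radius**2)
        for (r, c), amp in zip(centres_big, amps)
    ]
    cell_maps = [cm[crop] for cm in cell_maps_big]
    # tissue autofluorescence: broad violet-excited emission against which
    # vessels appear as dark shadows (the vessel-contrast reference channel)
    af = fingerprint_from_model(
        SpectrumModel("autofluorescence", 410, 520, ex_width=45, em_width=60), grid
    ).values
    af = af / af.max()
    sd = noise_sd(float(amps.mean()) if len(amps) else 1.0, snr)
    stacks = {}
    for li, laser in enumerate(grid.laser_wavelengths):
        planes = np.zeros((n_z, grid.n_bins, *shape))
        for b in range(grid.n_bins):
            chan = background_level * af[li, b] * vessel_world
            for cm, cls in zip(cell_maps, classes):
                fp = library[cls].values[li, b]
                if fp > 0:
                    chan = chan + fp * cm
            gc = library[GCAMP].values[li, b] if GCAMP in library.names else 0.0
            if gc > 0:
                for cm in cell_maps:
                    chan = chan + 0.3 * gc * cm
            for z in range(n_z):
                noisy = chan / n_z
                if sd > 0:
                    noisy = noisy + rng.normal(0.0, sd / n_z, size=shape)
                planes[z, b] = np.clip(noisy, 0.0, None)
        stacks[laser] = SpectralStack(planes, laser, pixel_size=pixel_size)
    # miniscope side: GCaMP-like contrast, inverse-warped into miniscope frame
    gcamp_big = 0.6 * vessel_big + sum(cell_maps_big)
    inv = transform.inverse()
    mini = apply_transform(gcamp_big, inv)[crop]
    mini = ndimage.gaussian_filter(mini, 1.0)
    if sd > 0:
        mini = mini + rng.normal(0.0, sd / 10.0, size=shape)
    # ROI masks in miniscope coordinates (big-frame warp shares the centre)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rows = np.array([c[0] for c in centres_big])
    cols = np.array([c[1] for c in centres_big])
    mrows, mcols = inv.apply_points(rows, cols, big)
    mrows, mcols = mrows - pad, mcols - pad
    masks, kept = [], []
    radius_mini = cell_radius / transform.scale
    for i, (mr, mc) in enumerate(zip(mrows, mcols)):
        sel = (yy - mr) ** 2 + (xx - mc) ** 2 <= radius_mini**2
        if sel.sum() == 0:
            continue
        masks.append(ROIMask.from_boolean(sel, f"cell{i:03d}"))
        kept.append(i)
    truth = GroundTruth(
        [f"cell{i:03d}" for i in kept],
        [(classes[i],) for i in kept],
        [(float(amps[i]),) for i in kept],
        perturbation={"snr": snr, "transform": transform},
    )
    reference = vessel_world + (0.0 if sd == 0 else rng.normal(0, sd / 10.0, shape))
    return stacks, mini, masks, truth, reference
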