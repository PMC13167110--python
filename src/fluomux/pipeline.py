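"""End-to-end orchestration: flatten -> register -> extract -> unmix -> behavior.

A single YAML run configuration drives the full flow; every stage writes its
intermediate outputs plus a manifest recording parameters, seed, and per-stage
status, so a rerun with the same config and inputs reproduces the outputs.
"""

from __future__ import annotations

import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .behavior import EventSeries, selectivity_counts, selectivity_table
from .register import (
    ImageRegistration,
    PreprocessParams,
    SearchGrid,
    SimilarityTransform,
    apply_transform_mask,
)
from .simulate import (
    GroundTruth,
    equal_distribution_config,
    simulate_image_pair,
    simulate_roi_dataset,
)
from .spectral import (
    default_library,
    fingerprints_to_frame,
    frame_to_fingerprints,
    read_fingerprint_table,
    write_fingerprint_table,
)
from .stacks import (
    extract_roi_spectrum,
    flatten_stack,
    masks_from_label_image,
    read_stack_tiff,
    write_stack_tiff,
)
from .unmix import classify_subject

__all__ = ["PipelineError", "load_config", "run_pipeline", "make_fixtures"]

log = logging.getLogger("fluomux")

STAGES = ("library", "flatten", "register", "extract", "unmix", "behavior")


class PipelineError(RuntimeError):
    """A stage failed; the manifest records which and why."""


DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "fluomux_out",
    "library": None,  # path to fingerprint table; None -> default parametric library
    "stacks": {},  # laser_nm -> tiff path
    "n_z": 1,
    "pixel_size_um": 2.0,
    "z_crop": None,
    "background_radius_um": 30.0,
    "miniscope_image": None,
    "masks": None,  # 16-bit label tiff in miniscope coordinates
    "reference": {"laser": 405.0, "emission_nm": 512.0, "band_nm": None},
    "preprocess": {
        "moving": {"sigma_denoise": 1.0, "sigma_background": 50.0, "blackhat_window": 11},
        "fixed": {"sigma_denoise": 2.0, "sigma_background": 100.0, "blackhat_window": 21},
    },
    "search": {
        "translation_extent": 60.0,
        "translation_step": 5.0,
        "rotation_extent": 15.0,
        "rotation_step": 5.0,
        "scale_range": [1.8, 2.0],
        "scale_step": 0.05,
        "learning_rate": 0.5,
    },
    "unmix": {"k": 1.5, "dual_pass": True, "assignable": None},
    "behavior": None,  # {"traces": csv, "events": csv, "window": 2.5, "alpha": 0.05, "fs": 20.0}
}


def load_config(path_or_dict) -> dict:
    """Load a run config, filling defaults; round-trips losslessly via YAML."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    cfg = {}
    for key, default in DEFAULTS.items():
        val = user.get(key, default)
        if isinstance(default, dict) and isinstance(val, dict):
            merged = dict(default)
            merged.update(val)
            val = merged
        cfg[key] = val
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _search_grid(cfg: dict) -> SearchGrid:
    s = cfg["search"]
    return SearchGrid(
        translation_extent=s["translation_extent"],
        translation_step=s["translation_step"],
        rotation_extent=s["rotation_extent"],
        rotation_step=s["rotation_step"],
        scale_range=tuple(s["scale_range"]),
        scale_step=s["scale_step"],
        learning_rate=s["learning_rate"],
    )


def _reference_image(flattened: dict, grid, ref_cfg: dict) -> np.ndarray:
    """Vessel-contrast reference: one emission bin, or a summed band_nm range."""
    laser = float(ref_cfg["laser"])
    if laser not in flattened:
        raise PipelineError(f"reference laser {laser} not among flattened stacks")
    centers = grid.bin_centers
    if ref_cfg.get("band_nm"):
        lo, hi = ref_cfg["band_nm"]
        sel = (centers >= lo) & (centers <= hi)
        if not sel.any():
            raise PipelineError(f"no emission bins inside band {lo}-{hi} nm")
        return flattened[laser][sel].sum(axis=0)
    b = int(np.argmin(np.abs(centers - float(ref_cfg["emission_nm"]))))
    return flattened[laser][b]


def run_pipeline(config, out_dir=None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    On stage failure the manifest records the stage and error, later stages
    are skipped, and :class:`PipelineError` is raised.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fluomux_version": __version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }
    state: dict = {}
    failed = None
    for stage in STAGES:
        try:
            skipped = _run_stage(stage, cfg, state, out)
            manifest["stages"][stage] = "skipped" if skipped else "complete"
            log.info("stage %s: %s", stage, manifest["stages"][stage])
        except Exception as exc:  # noqa: BLE001 - manifest must record any failure
            manifest["stages"][stage] = f"failed: {exc}"
            log.error("stage %s failed:\n%s", stage, traceback.format_exc())
            failed = (stage, exc)
            for later in STAGES[STAGES.index(stage) + 1 :]:
                manifest["stages"][later] = "skipped (earlier failure)"
            break
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_yaml_safe(manifest), fh, sort_keys=False)
    if failed:
        raise PipelineError(f"stage {failed[0]} failed: {failed[1]}") from failed[1]
    return manifest


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _run_stage(stage: str, cfg: dict, state: dict, out: Path) -> bool:
    """Run one stage; returns True if the stage was skipped (not configured)."""
    if stage == "library":
        lib = (
            read_fingerprint_table(cfg["library"])
            if cfg["library"]
            else default_library()
        )
        state["library"] = lib
        return False

    if stage == "flatten":
        if not cfg["stacks"]:
            raise PipelineError("no spectral stacks configured")
        lib = state["library"]
        flattened = {}
        crop = tuple(cfg["z_crop"]) if cfg["z_crop"] else None
        for laser, path in cfg["stacks"].items():
            laser = float(laser)
            stack = read_stack_tiff(
                path, laser, n_z=cfg["n_z"], pixel_size=cfg["pixel_size_um"]
            )
            flattened[laser] = flatten_stack(
                stack, z_crop=crop, background_radius_um=cfg["background_radius_um"]
            )
            # un-subtracted z-sum: dark vessels survive only here, so the
            # registration reference is taken from this image
            state.setdefault("raw_sums", {})[laser] = flatten_stack(
                stack, z_crop=crop, background_radius_um=None
            )
            tifffile.imwrite(
                out / f"flattened_{int(laser)}nm.tif",
                flattened[laser].astype(np.float32),
            )
        state["flattened"] = flattened
        return False

    if stage == "register":
        if cfg["miniscope_image"] is None:
            raise PipelineError("no miniscope image configured")
        moving = tifffile.imread(cfg["miniscope_image"]).astype(float)
        fixed = _reference_image(
            state["raw_sums"], state["library"].grid, cfg["reference"]
        )
        pp = cfg["preprocess"]
        reg = ImageRegistration(
            fixed,
            moving,
            search=_search_grid(cfg),
            fixed_params=PreprocessParams(**pp["fixed"]),
            moving_params=PreprocessParams(**pp["moving"]),
        )
        result = reg.fit()
        state["registration"] = result
        with open(out / "transform.yaml", "w") as fh:
            yaml.safe_dump(_yaml_safe(result.to_dict()), fh, sort_keys=False)
        (out / "registration_summary.txt").write_text(result.summary() + "\n")
        return False

    if stage == "extract":
        if cfg["masks"] is None:
            raise PipelineError("no ROI masks configured")
        labels = tifffile.imread(cfg["masks"])
        masks = masks_from_label_image(labels)
        if not masks:
            raise PipelineError("label image holds no ROIs")
        t = state["registration"].transform
        flattened = state["flattened"]
        shape = next(iter(flattened.values())).shape[1:]
        grid = state["library"].grid
        spectra, lost = [], []
        for m in masks:
            warped = apply_transform_mask(m, t, shape)
            if warped is None:
                lost.append(m.roi_id)
                continue
            spectra.append(extract_roi_spectrum(flattened, warped, grid))
        if lost:
            log.warning("ROIs mapped outside the confocal frame: %s", lost)
        state["spectra"] = spectra
        write_fingerprint_table(out / "roi_spectra.csv", spectra, grid)
        return False

    if stage == "unmix":
        u = cfg["unmix"]
        res = classify_subject(
            state["spectra"],
            state["library"],
            k=u["k"],
            dual_pass=u["dual_pass"],
            assignable=u["assignable"],
        )
        state["unmix"] = res
        res.to_frame().to_csv(out / "assignments.csv", index=False)
        (out / "unmix_summary.txt").write_text(res.summary() + "\n")
        return False

    if stage == "behavior":
        b = cfg["behavior"]
        if b is None:
            return True
        traces = pd.read_csv(b["traces"])
        events_df = pd.read_csv(b["events"])
        series = [
            EventSeries(str(name), tuple(sorted(sub["onset_s"])))
            for name, sub in events_df.groupby("behavior")
        ]
        results = selectivity_table(
            traces,
            series,
            fs=b.get("fs", 20.0),
            window=b.get("window", 2.5),
            alpha=b.get("alpha", 0.05),
        )
        identities = None
        if "unmix" in state:
            identities = {
                a.roi_id: a.primary for a in state["unmix"].assignments
            }
        pd.DataFrame([vars(r) for r in results]).to_csv(
            out / "selectivity.csv", index=False
        )
        selectivity_counts(results, identities).to_csv(
            out / "selectivity_counts.csv", index=False
        )
        return False

    raise PipelineError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# fixture generation

FIXTURE_KINDS = ("fingerprints", "roi_dataset", "image_pair")


def make_fixtures(kind: str, seed: int, out_dir) -> list[Path]:
    """Write ready-to-use synthetic inputs for the other pipeline commands."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib = default_library()
    written: list[Path] = []

    def emit(path):
        written.append(path)
        return path

    write_fingerprint_table(emit(out / "library.csv"), lib.fingerprints, lib.grid)
    if kind == "fingerprints":
        return written

    if kind == "roi_dataset":
        from .simulate import realistic_config

        cfg = realistic_config(seed=seed, n_rois=460)
        spectra, truth = simulate_roi_dataset(cfg, lib)
        write_fingerprint_table(emit(out / "roi_spectra.csv"), spectra, lib.grid)
        truth.to_frame().to_csv(emit(out / "ground_truth.csv"), index=False)
        return written

    transform = SimilarityTransform(10.0, -15.0, 5.0, 1.9)
    stacks, mini, masks, truth, _ = simulate_image_pair(seed, lib, transform)
    shape = mini.shape
    stack_paths = {}
    for laser, stack in stacks.items():
        p = emit(out / f"stack_{int(laser)}nm.tif")
        write_stack_tiff(p, stack)
        stack_paths[float(laser)] = str(p)
    tifffile.imwrite(emit(out / "miniscope.tif"), mini.astype(np.float32))
    labels = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        labels[m.rows, m.cols] = i
    tifffile.imwrite(emit(out / "masks.tif"), labels)
    # ROI ids in the truth table must match the label-image values
    truth.roi_ids = [str(i) for i in range(1, len(masks) + 1)]
    truth.to_frame().to_csv(emit(out / "ground_truth.csv"), index=False)
    first = next(iter(stacks.values()))
    run_cfg = {
        "seed": seed,
        "out_dir": str(out / "run"),
        "library": str(out / "library.csv"),
        "stacks": {float(l): str(p) for l, p in stack_paths.items()},
        "n_z": first.n_z,
        "pixel_size_um": first.pixel_size,
        "background_radius_um": 20.0,
        "miniscope_image": str(out / "miniscope.tif"),
        "masks": str(out / "masks.tif"),
        "preprocess": {
            "moving": {"sigma_denoise": 1.0, "sigma_background": 20.0, "blackhat_window": 11},
            "fixed": {"sigma_denoise": 1.0, "sigma_background": 20.0, "blackhat_window": 11},
        },
        "search": {
            "translation_extent": 20.0,
            "translation_step": 5.0,
            "rotation_extent": 10.0,
            "rotation_step": 5.0,
            "scale_range": [1.8, 2.0],
            "scale_step": 0.05,
            "learning_rate": 0.5,
        },
        "unmix": {
            "k": 1.5,
            "dual_pass": True,
            # the indicator is fit but is not an assignable identity in vivo
            "assignable": [n for n in lib.names if n != "GCaMP6s"],
        },
        "reference": {"laser": 405.0, "emission_nm": 512.0, "band_nm": [470.0, 560.0]},
    }
    with open(emit(out / "config.yaml"), "w") as fh:
        yaml.safe_dump(_yaml_safe(run_cfg), fh, sort_keys=False)
    return written
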