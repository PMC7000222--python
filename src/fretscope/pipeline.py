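"""End-to-end analysis driver.

Orders the standard stages — segmentation from the acceptor channel,
bleed-through-corrected FRET index, quadrant traces and HFQ/LFQ summary,
pulse-period spectra, sector kymograph, morphodynamics, and the
motility/activity correlation — and writes per-stage CSVs plus a JSON
summary stamped with the package version, a config hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .fret import BleedThroughCoefficients, compute_fret_index
from .io import read_frameset
from .morphodynamics import (boundary_velocity_map, fractional_changes,
                             motility_fret_correlation, near_membrane_signal)
from .segmentation import build_mask, quadrant_labels
from .spatiotemporal import (cell_dominant_period, compartment_summary,
                             dominant_period, quadrant_mean_traces,
                             sector_kymograph)

log = logging.getLogger("fretscope")


@dataclass
class PipelineConfig:
    """Paths, calibration, segmentation and stage toggles for one run."""

    donor_path: str
    fret_path: str
    acceptor_path: str
    out_dir: str = "fretscope_out"
    alpha_d: float = 0.55
    alpha_a: float = 0.028
    median_filter: bool = True
    threshold: float | None = None
    min_area_px: int = 50
    erosion_radius_px: int = 0
    run_quadrant: bool = True
    run_psd: bool = True
    run_sector: bool = True
    run_morpho: bool = True
    run_motility: bool = True
    n_boundary_samples: int = 100
    seed: int = 0

    def validate(self) -> None:
        missing = [p for p in (self.donor_path, self.fret_path,
                               self.acceptor_path) if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input stacks: {missing}")
        if not (0 <= self.alpha_d < 1 and 0 <= self.alpha_a < 1):
            raise ConfigError("bleed-through slopes must lie in [0, 1)")

    def digest(self) -> str:
        # out_dir does not influence any computed number
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload,
                                         sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested stages; returns the summary dict (also written to
    ``summary.json``).  Deterministic given inputs and seed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"package_version": __version__, "config_hash": config.digest(),
             "seed": config.seed}
    summary: dict = dict(stamp)

    frames = read_frameset(config.donor_path, config.fret_path,
                           config.acceptor_path)
    coeffs = BleedThroughCoefficients(config.alpha_d, config.alpha_a)
    fret_t = compute_fret_index(frames, coeffs,
                                median_filter=config.median_filter)
    mask = build_mask(frames.acceptor, threshold=config.threshold,
                      min_area_px=config.min_area_px,
                      erosion_radius_px=config.erosion_radius_px,
                      pixel_size_um=frames.pixel_size_um)

    traces = None
    if config.run_quadrant or config.run_psd:
        labels = quadrant_labels(mask)
        traces = quadrant_mean_traces(fret_t, labels,
                                      frames.frame_interval_min)
        df = pd.DataFrame(traces.mean_intensity.T,
                          columns=list(traces.quadrant_ids))
        df.insert(0, "time_min", traces.time_min)
        _write_csv(df, out / "quadrant_traces.csv", stamp)
        cs = compartment_summary(traces)
        summary["compartment"] = {
            "max_fret_hfq": cs.max_fret_hfq, "lfq_at_same_time":
            cs.lfq_at_same_time, "hfq_id": cs.hfq_id, "lfq_id": cs.lfq_id,
            "t_at_max_min": cs.t_at_max}

    if config.run_psd and traces is not None:
        rows = []
        for q, qid in enumerate(traces.quadrant_ids):
            try:
                psd = dominant_period(traces.mean_intensity[q],
                                      frames.frame_interval_min)
                rows.append({"quadrant": qid,
                             "dominant_frequency_per_min": psd.dominant_frequency,
                             "dominant_period_min": psd.dominant_period_min})
            except Exception as exc:  # flat quadrant: record, keep going
                log.warning("PSD for %s failed: %s", qid, exc)
        if rows:
            _write_csv(pd.DataFrame(rows), out / "psd.csv", stamp)
            summary["dominant_period_min"] = cell_dominant_period(traces)

    if config.run_sector:
        kymo = sector_kymograph(fret_t, mask,
                                frame_interval_min=frames.frame_interval_min)
        df = pd.DataFrame(kymo.mean_intensity,
                          index=kymo.distance_bins_px,
                          columns=kymo.time_min)
        df.index.name = "distance_px"
        _write_csv(df.reset_index(), out / "sector_kymograph.csv", stamp)
        summary["sector"] = {"arc_length_px": kymo.arc_length_px,
                             "arc_center_index": kymo.arc_center_index}

    if config.run_morpho:
        morpho = fractional_changes(mask)
        summary["morphodynamics"] = {
            "mean_fractional_area_change": morpho.mean_fractional_area_change,
            "mean_fractional_perimeter_change":
                morpho.mean_fractional_perimeter_change}
        _write_csv(pd.DataFrame({"area_px2": morpho.areas_px2,
                                 "perimeter_px": morpho.perimeters_px}),
                   out / "morphodynamics.csv", stamp)

    if config.run_motility:
        mmap = boundary_velocity_map(mask, frames.frame_interval_min,
                                     config.n_boundary_samples)
        sig = near_membrane_signal(fret_t, mask,
                                   n_boundary_samples=config.n_boundary_samples,
                                   n_frames=mask.n_frames - 1)
        mmap.near_membrane_signal = sig
        corr = motility_fret_correlation(mmap)
        _write_csv(pd.DataFrame({"bin_center": corr.bin_centers,
                                 "mean_motility_um_per_min":
                                     corr.mean_motility_per_bin,
                                 "n": corr.n_per_bin}),
                   out / "motility_bins.csv", stamp)
        summary["motility"] = {
            "spearman_rho": corr.spearman_rho,
            "cubic_coefficients": corr.cubic_coefficients,
            "fit_r2": corr.fit_r2}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_csv(df: pd.DataFrame, path: Path, stamp: dict) -> None:
    """CSV with a one-line provenance header comment."""
    with open(path, "w") as fh:
        fh.write(f"# fretscope {stamp['package_version']} "
                 f"config={stamp['config_hash']} seed={stamp['seed']}\n")
        df.to_csv(fh, index=False)
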