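"""End-to-end analysis: movie -> masks -> curves -> skeletons -> activities
-> pseudopods -> statistics (and optionally correlation with a second
channel).

Stages run in their natural order — segmentation, boundary smoothing,
skeletonization, pruning, per-pair difference maps and activity
detection, backward tracking, statistics — with per-frame pruning
thresholds resolved from each frame's own body length and the tracking
threshold from the mean perimeter.  All skeleton and difference-map
work happens on the rasterised smoothed boundary, so skeletons and
difference maps are mutually consistent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import activity as activity_mod
from . import boundary as boundary_mod
from . import correlation as correlation_mod
from . import segmentation as segmentation_mod
from . import skeleton as skeleton_mod
from . import stats as stats_mod
from . import tracking as tracking_mod
from .config import PipelineConfig
from .errors import DegenerateShape, NoCellFound

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    masks: list
    curves: list
    skeletons: list
    activities: list
    pseudopods: list
    cell_stats: object | None
    config: PipelineConfig
    smooth_masks: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config_resolved.yaml")
        segmentation_mod.write_masks_tiff(self.masks, out / "masks.tif")
        import pandas as pd
        pd.concat([c_to_df(c) for c in self.curves], ignore_index=True) \
            .to_csv(out / "curves.csv", index=False)
        pd.concat([s.to_dataframe() for s in self.skeletons],
                  ignore_index=True).to_csv(out / "skeletons.csv", index=False)
        activity_mod.activities_to_dataframe(self.activities) \
            .to_csv(out / "activities.csv", index=False)
        tracking_mod.pseudopods_to_dataframe(self.pseudopods) \
            .to_csv(out / "pseudopods.csv", index=False)
        cs = ({"empty": True} if self.cell_stats is None
              else self.cell_stats.to_json_dict())
        (out / "cell_stats.json").write_text(json.dumps(cs, indent=2))


def c_to_df(curve):
    import pandas as pd
    return pd.DataFrame({"frame": curve.frame_index,
                         "x": curve.samples[:, 1], "y": curve.samples[:, 0]})


def segment_movie(movie, cfg: PipelineConfig):
    return segmentation_mod.segment_movie(movie, min_area=cfg.min_area_px)


def analyze_movie(movie, cfg: PipelineConfig | None = None,
                  masks: list | None = None) -> PipelineResult:
    """Run the full pipeline on one movie.

    ``masks`` may be supplied (e.g. ground-truth segmentations); they
    are otherwise computed with the modality-appropriate method.
    """
    cfg = cfg or PipelineConfig(frame_interval_s=movie.frame_interval,
                                pixel_size_um=movie.pixel_size,
                                modality=movie.modality,
                                gradient=movie.gradient)
    if masks is None:
        masks = segment_movie(movie, cfg)

    curves, smooth_masks, skeletons = [], [], []
    for fr in masks:
        curve = boundary_mod.smooth_boundary(
            fr, smoothing=cfg.smoothing, n_control=cfg.n_control,
            n_iterations=cfg.spline_iterations)
        curves.append(curve)
        smask = curve.to_mask(fr.mask.shape)
        smooth_masks.append(smask)
        prune_cfg = skeleton_mod.PruningConfig.from_body_length(
            curve.body_length, r=cfg.r_ratio,
            p_factor=cfg.p_threshold_factor,
            prdist_factor=cfg.prdist_threshold_factor)
        try:
            skel = skeleton_mod.skeletonize(smask, frame_index=fr.frame_index)
            skel = skeleton_mod.prune(skel, curve, prune_cfg,
                                      single_pass=cfg.pruning_single_pass)
        except DegenerateShape:
            skel = skeleton_mod.Skeleton(
                graph=nx.MultiGraph(), shape=fr.mask.shape,
                frame_index=fr.frame_index, empty_flag=True)
        skeletons.append(skel)

    activities = []
    for n in range(len(masks) - 1):
        diff = activity_mod.difference_map(smooth_masks[n],
                                           smooth_masks[n + 1])
        acts = activity_mod.detect_activities(
            skeletons[n], skeletons[n + 1], diff, curves[n], curves[n + 1],
            gradient=cfg.gradient, frame_interval=cfg.frame_interval_s,
            min_component_area=cfg.min_component_area_px)
        activities.extend(acts)

    mean_perimeter = float(np.mean([c.perimeter for c in curves]))
    track_cfg = tracking_mod.TrackingConfig(
        T=cfg.T_s, alpha=cfg.alpha, beta=cfg.beta,
        R=cfg.cell_radius_px,
        dist_threshold=cfg.dist_threshold_factor * mean_perimeter)
    pods = tracking_mod.backward_track(activities, track_cfg,
                                       frame_interval=cfg.frame_interval_s)

    duration = len(masks) * cfg.frame_interval_s
    cell = (stats_mod.cell_stats(pods, duration, cfg.frame_interval_s,
                                 cfg.pixel_size_um) if pods else None)
    if cell is None:
        log.info("no activities detected: cell stats flagged empty")
    for name, objs in (("masks", masks), ("activities", activities),
                       ("pseudopods", pods)):
        log.info("pipeline stage %s: %d items", name, len(objs))
    return PipelineResult(masks=masks, curves=curves, skeletons=skeletons,
                          activities=activities, pseudopods=pods,
                          cell_stats=cell, config=cfg,
                          smooth_masks=smooth_masks)


def correlate_channel(result: PipelineResult, channel_movie,
                      normalization: str = "zscore"):
    """Correlate a second fluorescence channel with detected activities.

    Returns (activity matrix, normalised intensity matrix, correlation
    map, site-intensity pairs at 0 deg offset).
    """
    cfg = result.config
    n = len(result.curves)
    I = correlation_mod.build_intensity_matrix(
        channel_movie.frames[:n], result.curves,
        delta_theta=cfg.delta_theta_deg, band_px=cfg.band_px,
        gradient=cfg.gradient)
    I_n = I.normalized(normalization)
    A = correlation_mod.build_activity_matrix(result.activities,
                                              cfg.delta_theta_deg, n)
    cmap = correlation_mod.cross_correlate(A, I_n)
    pairs = correlation_mod.activity_site_intensity(result.activities, I_n)
    return A, I_n, cmap, pairs
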