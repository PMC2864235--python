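"""Shared fixtures: synthetic movies analysed once per session."""

import numpy as np
import pytest

from skelopod.config import PipelineConfig
from skelopod.pipeline import analyze_movie
from skelopod.synthetic import PseudopodEvent, render_movie


def eight_event_schedule():
    """Eight staggered grow-hold-retract pseudopods around the cell."""
    events = []
    for i, th in enumerate([0, 45, 90, 135, 180, -135, -90, -45]):
        events.append(PseudopodEvent(theta0=th, t_start=40 + 80 * i,
                                     duration=70, growth_rate=4,
                                     retract_rate=4, retract_delay=30))
    return events


def three_event_schedule():
    return [
        PseudopodEvent(theta0=0, t_start=30, duration=60, growth_rate=4),
        PseudopodEvent(theta0=120, t_start=50, duration=50, growth_rate=3,
                       retract_rate=3, retract_delay=20),
        PseudopodEvent(theta0=-120, t_start=0, duration=80, growth_rate=-3),
    ]


def match_activities(detected_df, truth_df, max_dist=8.0, max_dlen=2.5):
    """Greedy one-to-one matching of detected vs truth activities.

    Returns (recall, precision, n_matched).
    """
    used = set()
    matched = 0
    for _, r in truth_df.iterrows():
        cand = detected_df[(detected_df.frame == r["frame"])
                           & (detected_df.kind == r["kind"])]
        for i, c in cand.iterrows():
            if i in used:
                continue
            if (np.hypot(c.x_px - r.x, c.y_px - r.y) <= max_dist
                    and abs(c.length_px - r.length) <= max_dlen):
                matched += 1
                used.add(i)
                break
    recall = matched / len(truth_df) if len(truth_df) else 1.0
    precision = len(used) / len(detected_df) if len(detected_df) else 1.0
    return recall, precision, matched


@pytest.fixture(scope="session")
def movie100():
    """100-frame movie with 8 planted events, analysed once."""
    movie, truth = render_movie(events=eight_event_schedule(), n_frames=100,
                                seed=3)
    result = analyze_movie(movie, PipelineConfig())
    return movie, truth, result


@pytest.fixture(scope="session")
def movie20():
    """Short 3-event movie (growth, grow+retract, pure retraction)."""
    movie, truth = render_movie(events=three_event_schedule(), n_frames=20,
                                seed=1)
    result = analyze_movie(movie, PipelineConfig())
    return movie, truth, result
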