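"""Detect cell bodies on a synthetic movie and extract their traces.

Renders a small fluorescence movie with known soma positions, detects ROIs
on the time-averaged image (Otsu threshold + connected components), and
verifies the extracted traces against the generator's ground truth.
"""

import numpy as np

from calrecruit import (
    SimulationConfig,
    detect_rois,
    extract_traces,
    make_layout,
    match_rois_to_centroids,
    render_movie,
    render_trace,
    simulate_spike_trains,
    time_average,
)

config = SimulationConfig(n_neurons=16, duration_s=60.0, basal_rate_hz=0.2,
                          silent_fraction=0.0, seed=5)
trains = simulate_spike_trains(config, "basal")
traces = [render_trace(t, config) for t in trains]
layout = make_layout(16, (100, 100), radius_px=3.0)
movie = render_movie(traces, layout, (100, 100), background=5.0,
                     pixel_noise_sd=1.0, rng=np.random.default_rng(5))

avg = time_average(movie)
rois = detect_rois(avg, min_area_px=5, max_area_px=600)
matches = match_rois_to_centroids(rois, layout[:, :2], max_dist_px=3.0)
extracted = extract_traces(movie, rois)

print(f"movie: {movie.n_frames} frames of {movie.frame_shape}")
print(f"detected {len(rois)} ROIs; matched {len(matches)}/16 ground-truth somata")
by_id = {t.roi_id: t for t in extracted}
rs = [np.corrcoef(by_id[rid].values, traces[ti].values)[0, 1]
      for ti, rid in matches.items()]
print(f"extracted-vs-true trace correlation: median r = {np.median(rs):.3f}")
# High correlations mean the spatial averaging over detected footprints
# preserves each soma's temporal signal for the downstream dF/F stage.
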