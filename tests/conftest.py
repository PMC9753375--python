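import numpy as np
import pytest

import loomkit as lk


@pytest.fixture(scope="session")
def arena() -> lk.ArenaGeometry:
    return lk.ArenaGeometry()


@pytest.fixture(scope="session")
def protocol() -> lk.StimulusProtocol:
    return lk.StimulusProtocol()


@pytest.fixture(scope="session")
def freezing_trial(arena, protocol) -> lk.Trial:
    """One simulated trial with a planted 2.0-s freezing bout in the refuge."""
    rng = np.random.default_rng(7)
    scenario = lk.default_scenario(arena, freeze=True, rng=rng, acclimation_s=20, freeze_duration=2.0)
    return lk.simulate_trial(arena, protocol, scenario, seed=7)


@pytest.fixture(scope="session")
def nonfreezing_trial(arena, protocol) -> lk.Trial:
    rng = np.random.default_rng(8)
    scenario = lk.default_scenario(arena, freeze=False, rng=rng, acclimation_s=20)
    return lk.simulate_trial(arena, protocol, scenario, seed=8)


def make_motif_segments(motifs, reps=6, noise_sd=0.2, seed=0, window_frames=12, duration=2.0):
    """Noisy segments from planted motif templates, with class labels.

    Each rep yields ``duration*30/window_frames`` segments, so 6 reps of 2 s
    at the 12-frame window give 30 segments per class.
    """
    from loomkit.decomposition import compute_locomotion, egocentric_align, segment_nm

    rng = np.random.default_rng(seed)
    segments, truth = [], []
    for ci, m in enumerate(motifs):
        for rep in range(reps):
            snippet = lk.motif_template(m, duration, 30, seed=seed + 1000 * ci + rep)
            noisy = snippet.coords + rng.normal(0, noise_sd, snippet.coords.shape)
            series = lk.SkeletonSeries(noisy, 30)
            aligned = egocentric_align(series, trial_id=f"{m}-{rep}")
            speeds = compute_locomotion(series)
            segs = segment_nm(aligned, window_frames=window_frames, speeds=speeds)
            segments.extend(segs)
            truth.extend([ci] * len(segs))
    return segments, np.asarray(truth)
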