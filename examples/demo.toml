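# Demo pipeline configuration: a small simulated cohort analysed end to end.

[arena]
field_diameter = 50.0
trigger_diameter = 25.0
refuge_length = 50.0
refuge_width = 10.0

[protocol]
kind = "looming"

[simulation]
n_male = 5
n_female = 5
p_freeze_male = 0.7
p_freeze_female = 0.5
p_escape = 0.9
acclimation_s = 20.0
noise_sd = 0.2
frame_rate = 30.0
save_pose_trials = 1

[decomposition]
window_frames = 12
smooth_window = 5

[kernel]
max_segments = 250

[map]
n_neighbors = 15
min_dist = 0.1
k = 12

[detectors]
flight_speed_min = 20.0
freeze_speed_max = 1.0
freeze_min_s = 0.5

[stats]
alpha = 0.05
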