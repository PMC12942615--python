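# Default study configuration: a 16-subject, 2-trial cohort walking a
# ~10 m path at a comfortable pace, captured at 60 Hz by three systems.
# Every key mirrors a StudyConfig field; omitted keys keep their defaults.

n_subjects: 16            # cohort size
trials_per_subject: 2     # pooled as independent observations (32 cycles)
duration_s: 7.0           # seconds of walking per trial (>= 6 gait cycles)
sample_rate: 60.0         # Hz, all systems

# cohort distributions (means/SDs: stature in m, pace in m/s, step in m)
height_mean_m: 1.6925
height_sd_m: 0.0919
speed_mean_mps: 1.091
speed_sd_mps: 0.093
step_mean_m: 0.609
step_sd_m: 0.048

# per-system measurement noise: a preset name (ideal | bench | realistic)
# or an explicit mapping with keys mb_rot_sigma_deg, mb_pos_sigma_m,
# mml_rot_sigma_deg, mml_pos_sigma_m, sml_pixel_sigma
noise: realistic

# single-camera geometry
lateral_distance_m: 3.0   # lateral smartphone, on the subject's right
frontal_beyond_m: 2.0     # frontal smartphone, past the walkway end
focal_px: 1200.0          # pinhole focal length (1920x1080 sensor)
orthographic: false       # true replaces perspective with its far-field limit
audio_offset_s: 0.12      # emulated smartphone clock offset vs the lab clock

# confidence-based keypoint refinement
confidence_threshold: 0.3
interp_window: 5

seed: 0
reference: MB             # gold-standard arm for ICC / RMSE
self_comparison: false    # true: duplicate the reference arm (sanity mode)
rmse_aggregation: per_cycle   # or: pooled
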