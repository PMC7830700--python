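"""Band-pass + notch filtering and windowed RMS feature extraction.

Filters a synthetic trial through the acquisition chain (5-50 Hz
band-pass, 50 Hz notch) and extracts 500-ms RMS windows.  The printed
shape confirms the windowing arithmetic: 20 s at 250 Hz -> 40 windows
of 125 samples, i.e. two 4-channel RMS vectors per second.
"""

from semglove import Motion, SyntheticConfig, generate_trial, preprocess, rms_features

cfg = SyntheticConfig()
rec = generate_trial(Motion.SPHERICAL, cfg, seed=3)
filtered = preprocess(rec)  # 5-50 Hz band-pass, then 50 Hz notch
features = rms_features(filtered, window_ms=500)

print(f"recording: {rec.duration_s:g} s at {rec.sample_rate:g} Hz")
print(f"windows  : {features.n_windows} of {features.samples_per_window} samples "
      f"({1000 / features.window_ms:g} RMS vectors per second)")
print("first three feature rows (uV):")
print(features.to_frame().head(3).to_string(index=False))
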