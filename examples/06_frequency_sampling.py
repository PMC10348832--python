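"""Scenario: sampling by most frequently observed conformations.

Each frame's selection chance is proportional to the probability mass of
its property bin, so the sample concentrates on the states the trajectory
visits most.  Any externally computed per-frame measure (cavity volume,
rescoring energy) can replace the RMSD here via import_property_series.
"""

import tempfile

import mdsieve as m

series = m.generate_property_series(
    "mixture", {"mu1": 1.0, "sigma1": 0.1, "mu2": 5.0, "sigma2": 0.1,
                "pi": 0.9}, n_frames=4000, seed=6)

with tempfile.TemporaryDirectory() as tmp:
    sample = m.run_frequency_scenario(series, size=200, n_bins=20, seed=6,
                                      output_prefix=f"{tmp}/freq")
    dominant = (series.values[sample.frame_indices] < 3.0).mean()
    print(f"sampled {sample.actual_size} frames; "
          f"{100 * dominant:.1f}% from the dominant (90%) mode")

# Frequency weighting over-represents the dominant state relative to its
# 90% population share: a state's total selection mass scales with
# frequency x member count, i.e. with frequency squared.
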