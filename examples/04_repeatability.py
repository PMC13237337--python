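"""Retest repeatability of the five LGF measures across a small population.

Each synthetic subject draws its own middle-ear and reflex parameters;
repeats share the physiology and differ only in measurement noise and
drift.  ICC(C,k) near 1 means the measures separate subjects far better
than the measurement noise blurs them.  (The full-size harness — 30
subjects x 4 repeats — runs in the test suite.)
"""

from sweptmemr import icc_c_k, repeatability_table

table = repeatability_table(n_subjects=8, n_repeats=3, seed=7)
print(table.head(6).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
for col in ("max_tc_db", "delay_ms", "onset_db", "offset_db", "hysteresis_db"):
    cells = table.pivot(index="subject", columns="repeat", values=col).to_numpy()
    print(f"ICC(C,k) {col:14s}: {icc_c_k(cells):.3f}")
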