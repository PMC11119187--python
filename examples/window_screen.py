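"""Editing-window screen: does the nuclease care what sequence it cuts?

Simulates a library in which the 16-nt region between the two protospacers
(where the FokI dimer cuts) is randomised, with a planted preference: records
whose window carries TTTT at positions 6-9 are edited at 0.6, the rest at
0.08. Stratifying window motifs by estimated efficiency localises the
planted signal to the top stratum; a sequence-independent nuclease would
show flat motifs in every stratum.
"""

import numpy as np

from dimerscan import compute_editing_stats, make_window_library, simulate_library_reads, window_motif

rng = np.random.default_rng(0)
n = 400
hot = set(rng.choice(n, size=n // 4, replace=False).tolist())
windows = []
for i in range(n):
    w = "".join("ACGT"[j] for j in rng.integers(0, 4, 16))
    windows.append(w[:6] + "TTTT" + w[10:] if i in hot else w)

table = make_window_library(n, seed=1, windows=windows)
reads, _ = simulate_library_reads(
    table, lambda rec: 0.6 if rec.window16[6:10] == "TTTT" else 0.08, n_reads_per_record=40, seed=2
)
stats = compute_editing_stats(reads, table, max_mm=1)
result = window_motif(stats, n_strata=4)

print(f"overall max column IC: {result.overall.ic.max():.2f} bits")
for label, count, pfm in result.strata:
    ic = "empty" if pfm is None else np.array2string(pfm.ic, precision=2, floatmode="fixed")
    print(f"stratum {label} (n={count}): IC per column = {ic}")
print("the planted TTTT shows up as ~2-bit columns 6-9 in the top stratum only.")
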