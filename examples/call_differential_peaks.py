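"""Call FDR-controlled differential peaks on simulated data.

Fits the HMM, thresholds the differential-state posterior by controlling
the total FDR at 5%, merges contiguous windows into peaks and labels each
peak with the condition subset driving the difference.
"""

import numpy as np

from chromdiff import SimulationConfig, call_peaks, em_fit, simulate

sim = simulate(SimulationConfig(G=2, n=2, M=20_000, seed=42))
fit = em_fit(sim.dataset, seed=42)
peaks = call_peaks(fit, sim.dataset.windows, nominal=0.05)

d = peaks.decision
print(f"{d.n_called} windows pass the total-FDR cutoff "
      f"(estimated FDR {d.estimated_fdr:.4f} at nominal {d.nominal_level})")
print(f"{len(peaks)} merged peaks; the first five:\n")
cols = ["chrom", "start", "end", "n_windows", "mean_rho2", "pattern", "pattern_posterior"]
print(peaks.table[cols].head().to_string(index=False))

observed = np.mean(sim.true_state[d.called] != 1)
print(f"\nrealized window-level FDR against the simulation truth: {observed:.4f}")
print('pattern "1" means enrichment only in condition 1, "2" only in condition 2;')
print("pattern_posterior is the average mixture posterior of the winning pattern.")
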