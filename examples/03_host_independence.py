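"""Test whether circRNA accumulation is independent of host-gene expression.

Uses the count-level generator: circRNA junction counts rise 5-6x with age
while linear host counts stay flat.  Linear reads at the circRNA boundaries
give the circular:(circular+linear) ratio per replicate; a beta-binomial
likelihood-ratio test asks whether that ratio changes across time-points.
"""

import numpy as np

from circage import host_independence, simulate
from circage.genome_io import PipelineConfig

cfg = simulate.SimConfig(base_circ_mean=30.0, rng_seed=1)
pcfg = PipelineConfig()

circ, linear, libs = simulate.simulate_counts(cfg, n_circ=100)
res = host_independence.circ_host_ratio_test(circ, linear, libs, pcfg)
print(f"tested {len(res)} circRNAs (>= {pcfg.min_timepoint_reads} reads per "
      f"time-point); {int(res['independent'].sum())} called host-independent "
      f"at P<{pcfg.alpha}, FDR<{pcfg.fdr_threshold_ratio}")

cls = host_independence.classify_independent_changes(
    res, circ, linear, libs, ("D7", "L4"), pcfg
)
print(f"D7 vs L4: {cls['n_up']} independent circRNAs up, {cls['n_down']} down")
print(f"median circ log2FC  = {cls['density']['circ_log2fc'].median():.3f} "
      f"(planted: log2 5 = {np.log2(5):.3f})")
print(f"median linear log2FC = {cls['density']['linear_log2fc'].median():.3f} "
      f"(planted: 0, flat host expression)")
print(f"Pearson r(circ, linear log2FC) = {cls['pearson_r']:.3f}")
print("the vertical shift with near-zero horizontal shift and correlation is "
      "the signature of host-gene-independent circRNA accumulation.")
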