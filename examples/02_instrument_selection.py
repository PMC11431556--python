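"""Select instruments for one exposure/outcome pair.

The chain: genome-wide association threshold (p < 5e-5), LD clumping,
allele harmonization to a shared effect allele, removal of SNPs associated
with the outcome (p < 0.05), and the weak-instrument F >= 10 rule.
"""

from mrmediate import (InstrumentSelectionConfig, SimulationConfig,
                       harmonize, prepare_instruments, select_exposure_snps,
                       simulate_triple)
from mrmediate.instruments import f_statistic

exposure, _, outcome, truth = simulate_triple(SimulationConfig(seed=42))

selected = select_exposure_snps(exposure, 5e-5)
print(f"{selected.n_snp} of {exposure.n_snp} SNPs pass p < 5e-5 "
      f"({int((truth.gamma != 0).sum())} are truly causal)")

h = prepare_instruments(exposure, outcome, InstrumentSelectionConfig())
f = f_statistic(h.data["beta_x"], h.data["se_x"])
print(f"{h.k} instruments after clumping, harmonization and filters")
print(f"instrument strength: min F = {f.min():.1f}, median F = {sorted(f)[len(f)//2]:.1f}")

raw = harmonize(selected, outcome)
print(f"(harmonization alone kept {raw.k} shared SNPs; "
      f"{raw.k - h.k} removed by the outcome-association and F filters)")
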