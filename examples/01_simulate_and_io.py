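"""Generate a synthetic GWAS triple and round-trip it through TSV files.

The generator emulates a two-sample MR study design: a continuous exposure
panel, a continuous mediator, and a binary outcome on the log-odds scale,
each measured in non-overlapping samples.
"""

import tempfile
from pathlib import Path

from mrmediate import SimulationConfig, read_sumstats, simulate_triple, write_sumstats

cfg = SimulationConfig(seed=42)
exposure, mediator, outcome, truth = simulate_triple(cfg)

print(f"exposure: {exposure.n_snp} SNPs, n={cfg.n_exposure}")
print(f"mediator: {mediator.n_snp} SNPs, n={cfg.n_mediator}")
print(f"outcome (binary): {outcome.n_snp} SNPs, n={cfg.n_outcome}")
print(f"true total effect   {truth.true_total:.3f}  (log-odds per SD exposure)")
print(f"true mediated part  {truth.true_mediated:.3f}  "
      f"({truth.true_proportion_pct:.1f}% of the total)")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "exposure.tsv"
    write_sumstats(exposure, path)
    back = read_sumstats(path)
    print(f"TSV round-trip: {back.n_snp} SNPs re-read, "
          f"betas identical: {back.data['BETA'].equals(exposure.data['BETA'])}")
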