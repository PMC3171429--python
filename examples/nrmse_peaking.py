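"""The missing-value-rate peaking phenomenon.

Under quality-based masking, the hardest entries to impute are masked
first: at a tiny MV rate the masked set consists of the most extreme noise
outliers on the noisiest genes, so NRMSE starts high, dips as the masked
set broadens to more tractable entries, then rises again as data loss
bites.  Under uniform random masking the curve is flat-to-increasing — the
contrast explains why studies that mask at random see no peak.
"""

import warnings

import numpy as np

from mvimpute import ImputationConfig, SimulationParameters, generate_dataset, impute, nrmse

warnings.filterwarnings("ignore", message="BPCA did not converge")

RATES = [0.01, 0.05, 0.10, 0.20, 0.25]
REPS = 3

for mode in ("quality", "random"):
    means = []
    for rate in RATES:
        vals = []
        for rep in range(REPS):
            params = SimulationParameters(mv_rate=rate, mask_mode=mode, seed=29)
            train = generate_dataset(params, "train", repetition=rep)
            completed = impute(train.measured, train.mask,
                               ImputationConfig(method="BPCA"))
            vals.append(nrmse(train.signal, completed, train.mask))
        means.append(float(np.mean(vals)))
    curve = "  ".join(f"{r:.0%}:{m:.3f}" for r, m in zip(RATES, means))
    print(f"{mode:8s} BPCA NRMSE by MV rate ->  {curve}")

print("\nQuality masking shows the dip at an intermediate rate; random "
      "masking does not dip below its starting value.")
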