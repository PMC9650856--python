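"""Closed-loop check: simulate with known coefficients, re-estimate them.

Runs a few replicates of the recovery benchmark (15 animals x 300 steps,
known selection on aNDVI, dNDVI, elevation and TRI plus two experience
interactions) through the full pipeline and prints truth vs estimate with
robust confidence intervals.  With more replicates this becomes the package's
standing coverage/bias experiment (see scripts/acceptance.py).
"""
import logging
import warnings

import pandas as pd

from stepsel import experiments

logging.disable(logging.INFO)
warnings.filterwarnings("ignore")

reps = [experiments.recovery_replicate(seed) for seed in (101, 102, 103)]
out = pd.concat(reps, ignore_index=True)
out["lo"] = out["estimate"] - 1.96 * out["se_robust"]
out["hi"] = out["estimate"] + 1.96 * out["se_robust"]
out["covers"] = (out["lo"] <= out["truth"]) & (out["truth"] <= out["hi"])

for seed, grp in out.groupby("seed"):
    print(f"\nreplicate seed {seed}:")
    print(grp[["term", "truth", "estimate", "lo", "hi", "covers"]]
          .to_string(index=False, float_format=lambda v: f"{v:+.3f}"))

rate = out["covers"].mean()
print(f"\n95% robust CIs cover the generating value in {rate:.0%} of "
      f"{len(out)} term-replicates (expect ~95% over many replicates)")
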