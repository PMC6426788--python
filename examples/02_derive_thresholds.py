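"""Re-derive the survey's data-driven thresholds from synthetic data.

The survey derives three thresholds from the data itself: the p20 length
window (mean +/- 2 sd), the p20 bit-score cutoff (minimum over sequences of
the per-sequence maximal score), and the type I / type II metacaspase
interdomain limit (midpoint of the two 95% confidence bounds, 66 aa on the
published distance sets).
"""

import numpy as np

from caspmine import (
    SynthSpec,
    derive_interdomain_threshold,
    derive_length_range,
    derive_p20_cutoff,
    generate_proteome,
)

# length window from simulated domain lengths
rng = np.random.default_rng(0)
lengths = rng.normal(150.5, 24.75, size=2000).round().astype(int)
lo, hi = derive_length_range(lengths)
print(f"length window from 2000 simulated lengths: {lo}-{hi} aa "
      "(the survey's window is 101-200 aa)")

# interdomain threshold from planted linker lengths
spec = SynthSpec(seed=7, n_per_class={"metacaspase_I": 200, "metacaspase_II": 200},
                 n_decoys=0)
truth = generate_proteome(spec).truth
thr = derive_interdomain_threshold(
    truth[truth.architecture == "metacaspase_I"].interdomain_distance,
    truth[truth.architecture == "metacaspase_II"].interdomain_distance,
)
print(f"interdomain threshold from planted linkers: {thr} aa "
      "(closed form for the generator's Normal(20,10)/Normal(120,10) linkers: 70)")

# score cutoff: minimum of per-sequence maxima
scores = {"seqA": [40.0, 36.0], "seqB": [50.0], "seqC": [61.0, 38.5]}
print(f"p20 cutoff for {scores}: {derive_p20_cutoff(scores)} bits")
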