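"""Recover the nucleosome repeat from fragment length periodicity.

Okazaki fragment lengths ladder at multiples of the nucleosome repeat
because Pol delta tends to terminate at dyads. The autocorrelation of the
(envelope-detrended) length histogram peaks at the repeat length; an
unstructured length distribution is the negative control.
"""

import numpy as np

import okaseq as ok

records, _ = ok.simulate_fragments(ok.SimulationConfig(seed=4, n_fragments=50_000))
lag, score = ok.length_autocorrelation(records)
print(f"chromatin-phased ensemble: best lag {lag} nt, score {score:.3f}")

rng = np.random.default_rng(4)
flat = [ok.FragmentRecord("chrS1", int(s), int(s + l), "+")
        for s, l in zip(rng.integers(0, 900_000, 50_000),
                        rng.integers(50, 500, 50_000))]
flat_lag, flat_score = ok.length_autocorrelation(flat)
print(f"unstructured control:      best lag {flat_lag} nt, score {flat_score:.3f}")
print(f"score ratio (control / phased): {flat_score / score:.2f}")

# The phased ensemble recovers the configured 165-nt repeat; the control's
# best lag is arbitrary and its score a small fraction of the phased one.
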