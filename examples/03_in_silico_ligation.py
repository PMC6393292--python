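"""The in-silico ligase assay: signal lost when nicks are sealed.

Purified fragments are end-labeled (one signal unit per molecule shorter
than 1000 nt). T4 ligase seals every junction that is a precise nick;
merged molecules grow past the size cutoff and leave the quantified
region. The percent of signal lost therefore reads out the fraction of
junctions poised for ligation, compared here across replicates with a
paired t-test.
"""

import dataclasses

import okaseq as ok

base = ok.SimulationConfig(n_fragments=20_000)
for cond in ("WT", "rad27"):
    pairs = []
    for rep in range(3):
        config = dataclasses.replace(base, condition=cond, seed=10 + rep)
        records, _ = ok.simulate_fragments(config)
        merged = ok.ligate_in_silico(records)
        report = ok.percent_signal_lost(records, merged, size_cutoff=1000,
                                        replicate_id=f"{cond}_rep{rep}")
        pairs.append((float(report.signal_pre), float(report.signal_post)))
    t, df, p = ok.paired_t_test(pairs)
    lost = [100 * (a - b) / a for a, b in pairs]
    print(f"{cond}: signal lost {sum(lost)/3:.1f}% "
          f"(3 replicates; paired t = {t:.1f}, df = {df}, p = {p:.2e})")

# With 90% ligatable junctions (WT) nearly all fragments join chains that
# exceed 1000 nt, so most signal disappears; without Rad27 almost no
# junction is a sealable nick and the ladder persists.
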