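"""Check the per-target false-positive rate on empty networks.

With no true links, every inferred source is a false positive, and the
fraction of targets acquiring any source should match the test level
alpha. The exact 5th-95th percentile band of the matching binomial
average tells us what fluctuation to expect from the finite repeat count.
"""

from mtenet import InferenceSettings, empty_network_fpr_experiment

table = empty_network_fpr_experiment(
    n_list=[10],
    t=2_000,
    alpha_list=[0.05, 0.01],
    n_repeats=30,
    settings=InferenceSettings(),
    seed=0,
)
print(table.to_string(index=False))
# 'fpr' should sit inside [band_low, band_high] for each alpha: the
# hierarchical tests deliver the nominal per-target error rate.
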