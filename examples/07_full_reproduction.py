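"""One-command reproduction of the four-arm significance patterns.

Runs several independently seeded full studies (here a reduced count for
speed; the acceptance run uses 20) and votes per contrast: the expected
outcome is that single treatments shift contraction amplitude
non-significantly while acceleration and sarcomeric fluorescence shift
significantly, and the combined treatment is significantly depressed
everywhere.

Equivalent CLI:  cardiokin repro --seeds 20
"""

from cardiokin.pipeline import repro

result = repro(n_seeds=5, seed=0)
print(result.report())
# with only 5 seeds the vote is noisier than the 20-seed acceptance run;
# borderline displacement contrasts may occasionally flip on single seeds
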