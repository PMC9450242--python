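"""Recompute the source study's headline composites from its published
per-gender stratum values, and verify them.

The individual-level study data are not public; its printed stratum
prevalences are.  The package's own operations (gender adjustment,
within-stratum summation, conditional c/p rates) reproduce every headline
figure from them — e.g. total SUD 14.6%, any psychiatric disorder 26.7%,
and 22% of boys with a SUD also having a psychiatric disorder.
"""

import twophase as tp

for key, value in tp.headline_composites().items():
    print(f"{key:40s} {value:6.2f}")

print()
result = tp.verify_published()
print(result.to_string(index=False))
print("\nall reproduced:", bool(result["passed"].all()))
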