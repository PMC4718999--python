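"""Unsupervised category learning and the vigilance dial.

Trains a fast-learning ART network on 20 random binary feature patterns at
several vigilance levels.  Low vigilance accepts coarse matches, so many
patterns share a prototype; vigilance 1.0 demands a perfect match, so every
distinct exemplar gets its own category.
"""

import numpy as np

from saccart import train
from saccart.scenarios import gen_binary_patterns

patterns = gen_binary_patterns(n=20, d=25, overlap=0.4, seed=7)

print("vigilance  categories  resets")
for rho in (0.2, 0.5, 0.8, 1.0):
    model, traces = train(patterns, rho_base=rho)
    resets = sum(t.reset_count for t in traces)
    print(f"   {rho:.1f}        {len(model.committed):2d}        {resets:3d}")

print()
print("Each row is one training run on the same 20-pattern stream: higher")
print("vigilance forces more memory searches (resets) and commits more,")
print("more concrete categories; at 1.0 every distinct exemplar is its own.")
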