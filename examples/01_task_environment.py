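"""Generate a multiple-bandits session and look at its structure.

Each block has two decisions; decision 1's outcome follows the random walk
P, decision 2's follows Q, and within a decision the two actions always
pay P and 100 - P (anti-correlation).  The decision -> outcome-colour
mapping is hidden from the agent.
"""

import numpy as np

from creditassign import TaskConfig, generate_session
from creditassign.validate import same_side_run_lengths

config = TaskConfig(n_blocks=3, n_trials_per_block=100, walk_sd=15.0)
rng = np.random.default_rng(0)
blocks = generate_session(config, rng)

for i, block in enumerate(blocks):
    runs = same_side_run_lengths(block.P)
    print(f"block {i}: mapping decision1->colour{block.mapping[0]}, "
          f"P starts at {block.P[0]:>2d}, range {block.P.min()}-{block.P.max()}, "
          f"mean same-side run {np.mean(runs):.1f} trials")

# The anti-correlation identity: both candidate outcomes always sum to 100,
# so a win for one action is exactly a loss for the other.
block = blocks[0]
print("\ntrial 0 candidate outcomes for decision 1:",
      block.P[0], "and", 100 - block.P[0])
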