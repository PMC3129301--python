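#!/usr/bin/env python
"""Family phylogeny: NJ tree, bootstrap supports, genome-group classification.

Simulates a conserved-domain family with planted B-specific, D-specific and
mixed-origin groups (deep stems, shallow crowns), builds the K2P/NJ tree with
column-resampling bootstrap, classifies genome-specific clades, and checks the
planted memberships are recovered.  Writes the tree (Newick) and the group
table under results/.
"""

from pathlib import Path

import numpy as np

from retroclock import (
    GroupSpec,
    SimConfig,
    bootstrap_support,
    classify_genome_groups,
    simulate_family,
)
from retroclock.io_formats import write_aligned_fasta, write_newick_file

SEED = 20240903
N_BOOT = 100

out = Path("results")
out.mkdir(exist_ok=True)

cfg = SimConfig(domain_len=800)
rng = np.random.default_rng(SEED)
groups = [GroupSpec("gB", "B", 8, 6e6, 1.25e6),
          GroupSpec("gD", "D", 8, 6e6, 1.25e6),
          GroupSpec("gM", "A", 6, 6e6, 1.25e6)]
aln, labels, truths = simulate_family(cfg, groups, rng)
write_aligned_fasta(aln, out / "family.afa")

tree = bootstrap_support(aln, n_reps=N_BOOT, seed=SEED)
write_newick_file(tree, out / "family_tree.nwk")

got = classify_genome_groups(tree, labels, purity_threshold=0.90, min_size=5)
planted = {}
for t in truths:
    planted.setdefault(t.group_id, set()).add(t.element_id)
got_sets = {frozenset(g.members) for g in got}
recovered = sum(frozenset(m) in got_sets for m in planted.values())

with open(out / "family_groups.tsv", "w") as fh:
    fh.write(f"# seed {SEED}; bootstrap {N_BOOT}\n")
    fh.write("# group\tsize\tpurity\tmembers\n")
    for g in got:
        fh.write(f"{g.group_label}\t{g.size}\t{g.purity:.3f}"
                 f"\t{','.join(sorted(g.members))}\n")

supports = sorted(n.support for n in tree.root.walk()
                  if n is not tree.root and not n.is_tip())
print(f"classified groups: "
      f"{', '.join(f'{g.group_label} (n={g.size})' for g in got)}")
print(f"planted groups recovered exactly: {recovered}/{len(planted)}")
print(f"bootstrap supports range {supports[0]}-{supports[-1]} "
      f"({N_BOOT} replicates); tree -> results/family_tree.nwk")
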