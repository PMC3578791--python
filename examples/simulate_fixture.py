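"""Write a complete synthetic supergroup fixture to disk.

Produces a newick tree, a tip-to-group map, one aligned FASTA per group and
a JSON copy of the configuration — the inputs every other stage of the
pipeline consumes.
"""

import tempfile
from pathlib import Path

from protistdiv import GroupSpec, SimulationConfig
from protistdiv.synthetic_data import write_fixture

outdir = Path(tempfile.mkdtemp(prefix="protistdiv_fixture_"))
cfg = SimulationConfig(
    seed=1, seq_length=1800, base_rate=0.05,
    group_layout=[
        GroupSpec("MAST-like", 20, 0.7, depth=0.6),
        GroupSpec("diatom-like", 25, 0.3, depth=1.2),
        GroupSpec("labyrinthulid-like", 15, 0.4, depth=1.5),
    ],
)
tree, alignments = write_fixture(cfg, outdir)

print(f"fixture written to {outdir}:")
for p in sorted(outdir.iterdir()):
    print(f"  {p.name}")
print()
print(f"tree: {tree.n_tips} tips in {len(tree.groups())} monophyletic groups")
for gid, aln in alignments.items():
    print(f"  {gid}: {aln.n_seq} sequences x {aln.length} columns")
print()
print("The default gene layout embeds a 550-column V4V5-like region and a")
print("160-column V9-like region, both evolving 1.4x faster than background.")
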