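#!/usr/bin/env python
"""Predict the ring topology of the candidate core from the nisin A template.

Threads the core onto the conserved five-ring nisin fold and classifies each
bridge by its donor: Ser -> lanthionine (Lan), Thr -> 3-methyllanthionine
(MeLan).  Also reports the hinge residues (positions 20-22) and the
dehydratable Ser/Thr positions not claimed by any ring.
"""

import argparse
import json
from pathlib import Path

from lanthimine.topology import (
    NISIN_A_TEMPLATE,
    hinge_residues,
    thread_template,
    topology_as_dict,
    topology_schematic,
)
from lanthimine.variants import NISIN_S

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--core", default=NISIN_S)
parser.add_argument("--out", type=Path, default=Path("results/topology.json"))
args = parser.parse_args()
args.out.parent.mkdir(parents=True, exist_ok=True)

topo = thread_template(args.core)
block = topology_as_dict(topo)
block["hinge"] = hinge_residues(args.core)
block["template_hinge"] = hinge_residues(NISIN_A_TEMPLATE.core)
args.out.write_text(json.dumps(block, indent=2))

print(topology_schematic(args.core, topo))
for b in topo.bridges:
    donor = args.core[b.donor_pos - 1]
    acceptor = args.core[b.acceptor_pos - 1]
    print(f"ring {b.ring_label}: {b.type} {donor}{b.donor_pos}-{acceptor}{b.acceptor_pos}")
print(f"hinge (20-22): {block['hinge']} (template: {block['template_hinge']})")
print(f"dehydratable, unassigned: "
      f"{', '.join(args.core[p - 1] + str(p) for p in topo.unassigned_dehydratable)}")
print(f"wrote {args.out}")
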