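#!/usr/bin/env python
"""Compare the candidate core against known nisin variants.

Percent identities, the substitution list against the nisin A template,
residues unique to the candidate within the panel, and a neighbor-joining
dendrogram on p-distances.
"""

import argparse
import json
from pathlib import Path

from lanthimine import io_formats as io
from lanthimine.cli import compare_core
from lanthimine.variants import panel_from_records, reference_panel

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--panel", type=Path, default=None,
                    help="panel FASTA (default: packaged nisin A/F/S cores)")
parser.add_argument("--query", default="nisin_S")
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

panel = (panel_from_records(io.read_fasta(args.panel, "protein"))
         if args.panel else reference_panel())
block = compare_core(args.query, panel)
(args.outdir / "comparison.json").write_text(json.dumps(block, indent=2))
if block["newick"]:
    (args.outdir / "variants.nwk").write_text(block["newick"] + "\n")

for name, ident in sorted(block["identities"].items(), key=lambda kv: -kv[1]):
    subs = block["substitutions"][name]
    print(f"{args.query} vs {name}: {ident:.2f}% identity, "
          f"{len(subs)} substitution(s): {', '.join(subs) or '-'}")
print(f"unique residues of {args.query} in this panel: "
      f"{', '.join(block['unique_residues'])}")
if block["newick"]:
    print(f"NJ tree: {block['newick']}")
print(f"wrote {args.outdir}/comparison.json")
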