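#!/usr/bin/env python
"""Generate the synthetic study dataset with known ground truth.

Emulates the discovery inputs: a bacterial genome with an embedded
nisin-family precursor gene (25-aa leader ending in Lys + the 34-aa nisin S
core), an intact MALDI-style peak list carrying the 8-fold dehydrated core
mass, and a targeted-MS fragment m/z list.  Ground truth is serialized next
to each file so downstream stages can be checked exactly.
"""

import argparse
from pathlib import Path

from lanthimine import io_formats as io
from lanthimine.synthetic import embed_cluster, make_precursor, simulate_peaks
from lanthimine.variants import NISIN_S

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

precursor = make_precursor(NISIN_S, leader_len=25, minus1="K", seed=args.seed)
genome, truth_g = embed_cluster(10000, precursor, strand="+", seed=args.seed)
io.write_fasta([genome], args.outdir / "genome.fasta")
truth_g.to_json(args.outdir / "genome.truth.json")

intact, frags, truth_p = simulate_peaks(
    NISIN_S, n_dehydrations=8, jitter_sd=0.02 / 3, n_decoys=20,
    dropout_p=0.0, seed=args.seed,
)
io.write_peaklist(intact, args.outdir / "intact_peaks.tsv")
io.write_peaklist(frags, args.outdir / "fragment_peaks.tsv")
truth_p.to_json(args.outdir / "peaks.truth.json")

print(f"genome: {len(genome.residues)} nt, precursor planted at "
      f"[{truth_g.orf_start}, {truth_g.orf_end}) on strand {truth_g.strand}")
print(f"peaks: {len(intact)} intact, {len(frags)} fragment "
      f"(incl. {len(truth_p.decoy_peaks)} decoys)")
print(f"wrote {args.outdir}/")
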