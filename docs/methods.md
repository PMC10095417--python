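# Methods

## Model and assumptions

The pipeline treats a lanthipeptide discovery as a chain of independent,
individually checkable inferences over one candidate core peptide.

**Precursor model.** A nisin-family precursor is a single ORF encoding a
leader peptide followed immediately by the mature core, with no follower
peptide. The core is therefore taken to extend from the matched window to the
ORF's C-terminus, and the leader is everything before it. The residue at
position −1 (last leader residue) is classified Arg/Lys/other because it
determines protease compatibility at the cleavage site.

**Mining metric.** Candidate scoring uses ungapped sliding-window percent
identity of each panel core against the ORF protein. Mature nisin cores are
short (31–35 aa) and positionally comparable, and the comparisons the method
must reproduce are themselves percent-identity based, so a profile model or
gapped aligner would add machinery without changing the decisions. The cost
is insensitivity to indel-containing homologs; those are out of scope.

**Dehydration accounting.** Maturation removes one water (mono 18.010565 Da,
avg 18.0153 Da) per dehydrated Ser/Thr. Given a deduced unmodified mass and
an observed intact mass, the dehydration count is the nearest non-negative
integer of waters; the leftover residual is always reported, and the count
must not exceed the core's Ser+Thr capacity. Intact reconciliation defaults
to **average** masses (linear-mode MALDI reports average-like masses, and the
deduced intact value reproduces only under average masses), while fragment
work is **monoisotopic** (high-resolution LC-MS). Neutral mass is the
canonical quantity everywhere; protonation enters only when computing
m/z = (M + z·1.007276)/z with the bare-proton convention, which reproduces
detected fragment m/z values at 2 dp.

**Digestion and modification forms.** Trypsin cleaves after K/R except
before P (the plain proline rule; the rarer Keil exceptions are deliberately
not modelled — the test suite cross-checks against an independent digestion
engine driven by the same rule). Carbamidomethyl-Cys (+57.02146 Da) is fixed;
Met oxidation (+15.994915 Da) is variable up to two sites. Positional isomers
with equal modification multisets collapse to one inclusion-list row, since a
targeted method selects precursors by mass, not by site.

**Topology threading.** All natural nisin variants share the five-ring fold,
so the template's bridge positions (A 3–7, B 8–11, C 13–19, D 23–26,
E 25–28) are mapped positionally onto an equal-length core; threading
validates donor ∈ {S, T} and acceptor = C at each mapped position and fails
loudly naming the violated rings. Cores of different length are placed by a
gapless-offset alignment that maximizes identity over the overlap (ties to
the smallest offset), which in practice anchors on the near-invariant ring-A
region. The prediction is a structural hypothesis: threading says nothing
about which non-ring Ser/Thr carry Dha/Dhb, so those are reported as
"dehydratable, unassigned".

**Variant comparison.** p-distance (fraction of mismatching positions) on
positionally aligned cores, and neighbor joining (Saitou–Nei Q-criterion) on
that matrix. Model-corrected distances would be overkill for near-identical
34-mers and would not change neighbor relations. NJ is implemented in the
package with Q-ties broken by the lowest index pair and negative branch
lengths clamped to zero; tests verify exact metric recovery on additive
matrices and agreement with an independent NJ implementation.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| mining `min_identity_pct` | 40 | % | empirically zero false positives on random 10 kb genomes while recovering cores at ≥ 79% family identity |
| mining `min_protein_len` | 30 | aa | precursors are ~55–60 aa; 30 keeps the ORF set small without risking the target |
| `family_threshold_pct` (annotation) | 40 | % | same basis as mining |
| `truncation_ratio` | 0.8 | fraction | a product < 80% of its reference length with family-level identity is flagged as truncated |
| m/z match tolerance | 0.02 | Th | high-resolution precursor scans; rejects the one stray reported m/z value without losing true matches |
| intact match tolerance | 0.5 | Da | linear-mode MALDI mass accuracy |
| charges | 2–4 | — | the charge range a targeted method selects for peptides of this size |
| `max_variable` oxidations | 2 | — | the Met-containing fragment has two Met |
| `max_missed` cleavages | 0 | — | observed fragment tables are fully cleaved; configurable upward |

## Synthetic data: what it emulates and what it does not

`synthetic.make_precursor` / `embed_cluster` build a Met-initiated random
leader of chosen length and −1 residue, reverse-translate the precursor with
uniform codon choice under the standard code, and plant it (with a guarding
in-frame stop immediately upstream, so the planted ORF's start is exact) at a
seeded position on either strand of a uniform-ACGT background genome.
`simulate_peaks` emits the dehydrated intact mass and all inclusion-list m/z
values with Gaussian jitter, Bernoulli dropout, and uniform decoys over the
observed range ± 50 Da. `mutate_panel` plants exact Hamming distances.

Not emulated: GC skew and codon bias (mining is similarity-based and
composition-insensitive), isotope envelopes and intensity structure,
retention time, chimeric/assembly artifacts, and real MS2 spectra. Passing
tests therefore demonstrate correctness of the inference chain given peaks
and sequences, not robustness to raw-instrument artifacts.

Default generator settings mirror the study conditions the pipeline targets:
a 25-aa leader ending in Lys, a 34-aa core with eight dehydrations, fragment
jitter at one third of the matching tolerance, 20 decoys, and 10 kb genomes.

## Numerical choices

- Residue masses come from pyteomics' standard tables (monoisotopic) and
  from the same elemental compositions under average element masses; nothing
  mass-critical is typed by hand. The constants can be exported as TSV for
  diffing (`masses.export_constants`).
- Internal computation is full precision; display rounding is 2 dp for
  fragment masses and nearest integer for intact masses.
- Peak matching assigns each target its nearest peak, ties toward the lower
  value; one peak may satisfy several targets (charge states and isomers of
  one fragment can share a peak within tolerance).
- Reports use 1-based inclusive coordinates; internals are 0-based half-open.
- Candidate ranking ties break by (identity desc, contig asc, start asc);
  all outputs are byte-deterministic for fixed inputs and seed.

## Known limitations

- Ungapped mining misses precursors with indels relative to every panel
  member, and the ungapped "pad-with-mismatches" global identity used for
  cluster annotation under-scores homologs with large internal indels.
- The threading module cannot distinguish alternative ring topologies with
  identical donor/acceptor classes, and does not predict Dha/Dhb placement;
  chemical confirmation requires MS/MS or NMR, which is out of scope.
- The singly-reported stray detected m/z value that no protonation state of
  its fragment reproduces is treated as unexplained and is simply not matched
  at the default tolerance; no attempt is made to rationalize it.
- Neighbor joining on three taxa returns the (unique) star resolution; no
  bootstrap support is computed.
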