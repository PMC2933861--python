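# dinuqc

Genome-composition signals for assembly quality control.

When chromosome pseudomolecules are built from whole-genome-shotgun
scaffolds, genetic markers order and orient most of them — but marker
resolution collapses in centromeric and pericentromeric regions, where
recombination is rare. `dinuqc` computes two windowed composition signals
that expose large-scale structure in exactly those regions, and uses them to
flag scaffolds whose placement or orientation breaks an otherwise smooth
compositional gradient:

1. **Dinucleotide signature difference (δ\*).** The signature of a sequence
   is the vector of 16 odds ratios ρ\*_XY = f_XY / (f_X·f_Y), computed after
   pooling counts with the reverse complement (so ρ\*_XY = ρ\*_revcomp(XY)).
   The distance between two signatures is

       δ*(f, g) = (1/16) Σ_XY | ρ*_XY(f) − ρ*_XY(g) |.

   δ\* between each 50 kb window and the genome-wide signature is near zero
   for compositionally homogeneous DNA and spikes sharply over centromeric
   satellite arrays, whose CG-enriched monomers have a signature unlike the
   rest of the genome. In random 50 kb windows a defined ρ\*_XY leaves
   (0.78, 1.23) less than one time in a thousand.

2. **Nearest-neighbor binding energy.** Duplex stability per dinucleotide
   step, averaged over each 50 kb window using the consensus ΔG° table
   (10 unique pairs at 37 °C, e.g. AA/TT −1.00, CC/GG −1.84, GC −2.24
   kcal/mol; reported as a positive magnitude). Window energy tracks (C+G)
   content almost perfectly and rises over repeat-dense pericentromeres,
   producing broad gradients useful for orienting scaffolds.

On top of the profiles, the `assembly_qc` module overlays an AGP/BED scaffold
layout, scores the discontinuity at every scaffold junction (|mean of k
windows on each side|), and evaluates orientation flips by reversing a
scaffold's window order (exact for these strand-symmetric metrics). The
`repeats` module finds satellite monomer matches (ungapped, ≥ 90 % identity)
and chains them into tandem arrays using a 10×-monomer-length gap rule, plus
a lag-match periodicity scan. The `synthetic` module generates chromosomes
with known architecture — GC-0.32 arms, a GC-0.37 pericentromere rich in
GC-0.39 LTR-like elements, a CG-enriched ~91 bp satellite array — and shreds
them into scaffold layouts with secretly flipped subsets, providing ground
truth for everything above.

## Worked example

```python
import numpy as np
from dinuqc import (default_genome_spec, make_genome, energy_profile,
                    gc_profile, profile_correlation, genome_signature,
                    delta_profile)
from dinuqc.assembly_qc import region_stats

genome, truth = make_genome(default_genome_spec(seed=11))
chrom, seq = next(iter(genome.items()))

eprof = energy_profile(seq, sequence_id=chrom)          # 50 kb windows
gprof = gc_profile(seq, window_size=50_000, sequence_id=chrom)
print(region_stats(eprof, truth.region_boundaries()).round(4))
print("corr(energy, GC) =", round(profile_correlation(eprof, gprof), 4))

dprof = delta_profile(seq, genome_signature(genome), sequence_id=chrom)
i = int(np.nanargmax(dprof.values))
print("peak delta* window:", dprof.windows[i], "value", round(dprof.values[i], 3))
```

Output:

```
 region    start      end    n   mean     sd
      0        0  5000000  100 1.2036 0.0036
      1  5000000 10000000  100 1.2649 0.0325
      2 10000000 15000000  100 1.2027 0.0040
corr(energy, GC) = 0.9902
peak delta* window: (7450000, 7500000) value 0.419
```

The euchromatic arms average 1.204 kcal/mol per dinucleotide with very low
scatter, while the pericentromere averages 1.265 with ten-fold higher
variability — the broad peak that makes mis-oriented scaffolds visible.
Binding energy and GC are interchangeable (r = 0.990). The δ\* profile is
flat (median ≈ 0.013) except for a single ~0.4 peak over windows
7.45–7.50 Mb, inside the generator's true satellite array (7.40–7.60 Mb).

The same pipelines are available from the shell:

```sh
dinuqc simulate --seed 11 -o sim
dinuqc profile sim/genome.fa --metric binding-energy -o energy.bedgraph
dinuqc shred sim/genome.fa --fraction-flipped 0.3 --seed 2 -o shredded
dinuqc suggest-flips shredded/assembly.fa shredded/layout.agp -o flips.tsv
dinuqc arrays sim/genome.fa monomer.fa -o arrays.bed
```

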