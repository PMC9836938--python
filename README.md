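# macrocode

Computational support for genetically programmed cell-based synthesis of
non-natural peptide and depsipeptide macrocycles in codon-compressed
*E. coli*.

In a Syn61Δ3-type host the sense codons TCG and TCA and the amber stop
TAG — together with their decoding tRNAs and release factor 1 — have been
removed from the genome, freeing three codons. Synthetic genes carrying
reintroduced TCG/TAG codons can then direct non-canonical monomers
(ncAAs and alpha hydroxy acids) into short peptides that are excised and
cyclized into macrocycles; hydroxy-acid incorporation places ester bonds
in the backbone, giving depsipeptides. `macrocode` implements the
bookkeeping that such a programme needs:

- **chemistry** — elemental-formula arithmetic over embedded IUPAC mass
  tables (monoisotopic / average / nominal), a registry of the canonical
  amino acids plus 16 non-canonical monomers, ion m/z, and modification
  deltas (Boc loss −C5H8O2, azide→amine reduction −N2+H2).
- **recoding** — frame-aware codon compression (TCG→AGC, TCA→AGT,
  TAG→TAA), compliance validation, and translation under reassignment
  schemes (TCG→monomer A, TAG→monomer B; eight schemes ship as data).
- **design** — macrocycle-template instantiation, neutral/ion masses of
  linear and cyclic species (linear = Σ residues + H2O; cyclic = Σ
  residues), ester-hydrolysis product enumeration, and masses of
  single-substitution carrier proteins and their ester-cleavage fragments.
- **fragmentation** — an *n*-ring opens into *n* rotationally related
  linear sequences; theoretical a/b/y ions per opening
  (b_i = Σ residues + H⁺, a_i = b_i − CO, y_i = Σ suffix + H2O + H⁺) and
  tolerance-based annotation of observed peak lists.
- **orthogonality** — identification of mutually orthogonal
  synthetase/monomer pairs from RFU/OD600 activity matrices: (aaRS1, m1)
  pairs with (aaRS2, m2) when each enzyme is active (>10,000 RFU/OD600)
  with its own monomer and inactive (<2,500 by default, configurable)
  with the other's, across synthetase classes only, with excluded cells
  inert; plus projection to unique substrate pairings and a threshold
  sweep.
- **quantification** — gel-fluorescence standard curves on replicate
  means, internal-standard correction, and the visible-control zero rule.
- **synthetic** — seeded generators (activity matrices with planted
  ground-truth pairs, coding sequences with planted target codons,
  fragment spectra with planted ions and decoys) so the whole pipeline
  is testable offline.

## Worked example

```python
from macrocode import (load_registry, load_schemes, MacrocycleTemplate,
                       instantiate, ion_mz, linearize, theoretical_ions)

registry = load_registry()
schemes = load_schemes()

# 5-slot ring: three canonical residues plus the A and B placeholders,
# instantiated under scheme rs6 (A = AlkynK-OH, B = pAzF)
template = MacrocycleTemplate("SanA_like", ("L", "Ala", "V", "A", "B"))
species = instantiate(template, schemes["rs6"], registry)
print("ring:", "-".join(species.monomers))
print("ester bonds:", sorted(species.ester_positions))
neutral = species.neutral_mass()
print(f"cyclic neutral mass: {neutral.value:.4f} Da")
print(f"[M+H]+: {ion_mz(neutral, 'M+H', 1):.4f}")
lin = linearize(species)[0]
print("opened bond", lin.opened_bond, "->", "-".join(lin.monomers))
for ion in theoretical_ions(lin)[:6]:
    print(f"  {ion.label}: {ion.mz:.4f}")
```

prints

```
ring: L-Ala-V-8-5
ester bonds: [2]
cyclic neutral mass: 682.3439 Da
[M+H]+: 683.3511
opened bond 0 -> Ala-V-8-5-L
  b1: 72.0444
  a1: 44.0495
  y1: 132.1019
  b2: 171.1128
  a2: 143.1179
  y2: 320.1717
```

The ring carries one ester bond (bond 2, donated into the alpha-hydroxyl
of hydroxy acid 8, AlkynK-OH). The singly protonated precursor of the
cyclic species is m/z 683.35; each of the five ring openings yields its
own b/a/y ladder, and annotating an observed MS/MS peak list against all
five (`macrocode.annotate`) is how cyclicity and monomer order are
confirmed. The same machinery is available from the shell, e.g.

```sh
$ macrocode mass C5H8O2 --mode nominal
100
```

— the 100 Da neutral loss of a tert-butoxycarbonyl group, the satellite
peak expected below any Boc-carrying species.

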