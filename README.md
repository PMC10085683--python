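# chromonema

Analytics and polymer simulation for the helical coiling of metaphase
chromatids.

Mitotic chromatids of species with large chromosomes (the package's defaults
follow barley, *Hordeum vulgare*) condense into a **chromonema**: a ~400 nm
thick chromatin thread wound into a helix whose turns each cover tens of
megabases.  In Hi-C data this shows up as a local "bump" in the contact
probability *P(s)* at the genomic size of one helical turn, on top of the
exponential-like short-range decay.  `chromonema` provides the computational
side of that analysis for people working with metaphase Hi-C and chromosome
polymer models:

* **`hic_contacts`** — parse 4DN-style `.pairs` files, compute log-binned
  contact probability *P(s)* (observed pairs / possible locus pairs per
  distance bin, 100 kb – 1 Gb), log-log derivatives and
  metaphase/interphase ratio curves.
* **`turnlength`** — estimate the local helical turn length *T_l* by fitting
  `A·exp(−s/λ) + B·exp(−(s−μ)²/2σ²)` to the contact-distance histogram of
  each 5 Mb region; the Gaussian centre μ is the turn length.
* **`helix_geometry`** — build the variable-radius helical path from a
  turn-length profile:

      n_i = l_i / m / l_0                     monomers per turn
      z_i = z_{i−1} + H/n_i ,  θ_i = θ_{i−1} + 360°/n_i
      (d·n_i)² = (2π·r_i)² + H²               radius (H = 400 nm turn height)

  count helical turns (cycles of cos θ), extrapolate physical chromosome
  length, compute chromatin packing density, and classify sister-chromatid
  exchange (SCE) segments against the chromonema's geometric constraints.
* **`polymer_sim`** — coarse-grained bottle-brush Langevin simulator:
  nested exponential-length major/minor loops, harmonic bonds (10 nm rest,
  1 nm wiggle), angular stiffness (1 kBT/rad²), soft truncated repulsion
  (1.5 kBT barrier, chain-crossing permitted, mimicking topoisomerase II),
  loop bases tethered (4 kBT/nm²) to a helical path, optional cylindrical
  confinement (10 kBT/nm², 11³ nm³ per monomer); a half-helical variant
  folds the path with |x|.
* **`model_contacts`** — contact read-out of simulated conformations
  (51 nm contact radius), *P(s)* normalized to 1 at 100 kb, model/Hi-C
  divergence metrics, turn-peak detection.
* **`synthetic_data`** — generators for metaphase-like pairs
  (exponential + Gaussian bump), interphase-like power-law pairs and ideal
  helical conformations, so the whole pipeline runs without any downloads.

## Worked example

Generate synthetic metaphase contacts with a 30 Mb helical signal, estimate
the turn length, build the helical path and count turns:

```python
import chromonema as cn

spec = cn.HelicalSignalSpec(chrom_length=200_000_000, turn_length=30_000_000,
                            n_pairs=4_000_000, seed=1)
pairs = cn.generate_helical_pairs(spec)

profile = cn.turn_length_profile(pairs)            # 5 Mb regions
df = profile.to_frame()
interior = df[(df.start >= 30e6) & (df.end <= 170e6)]
print(f"median turn length: {interior.turn_length.median()/1e6:.2f} Mb")

path = cn.build_helical_path(30_000_000, span_bp=150_000_000,
                             params=cn.HelixParams(m=1_000_000, l0=1))
print(f"turns: {cn.count_turns(path):.1f}, extent: {path.z_extent_nm:.0f} nm")
print(f"density: {cn.chromatin_density(24.75, 600):.4f} um^3/Mb")
```

prints

```
median turn length: 29.98 Mb
turns: 5.0, extent: 2000 nm
density: 0.0413 um^3/Mb
```

The median regional estimate recovers the generated 30 Mb turn length; a
150 Mb span at 30 Mb per turn makes exactly 5 helical turns of 400 nm each;
and a 24.75 µm³ chromatid holding 600 Mb packs 1 Mb of chromatin per
~0.041 µm³.

The same operations are available from the shell:

```bash
chromonema synth pairs --chrom-length 200000000 --turn-length 30000000 \
    --n-pairs 4000000 --seed 1 --out synth.pairs
chromonema turnlength --pairs synth.pairs --out tl
chromonema helixpath --constant-turn 30000000 --span 150000000
```

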