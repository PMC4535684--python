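# dafish

Quantification of **differential accessibility (DA)** between homologous
metaphase chromosomes from fluorescence *in situ* hybridization (FISH)
images.

At ~10 % of genomic loci, short single-copy FISH probes hybridize
reproducibly more strongly to one homolog than to the other on mitotic
metaphase chromosomes — a stable, directionally consistent chromatin mark
related to local chromosome compaction. `dafish` implements the image
analysis and statistics needed to measure and call this phenomenon, and to
test whether a chromatin-modifying treatment (e.g. inhibition of
topoisomerase IIα with ICRF-193) equalizes accessibility between homologs:

1. **Segmentation** — each probe signal's boundary is delineated by an
   active contour (snake) driven by a **gradient vector flow (GVF)** field
   computed from an edge map of the image. GVF diffuses the edge gradient
   so the contour can be initialized far from the spot and still converge.
2. **Quantification** — background-corrected integrated intensities
   $I_A, I_B$ inside the two contours, and the normalized inter-homolog
   difference

   $$d = \frac{|I_A - I_B|}{I_A + I_B} \in [0, 1],$$

   where $d = 0$ means equal accessibility and $d = 1$ means signal absent
   on one homolog. $d$ is invariant to the overall intensity scale.
3. **DA calling** — a cell *shows DA* when $d$ exceeds a per-cell threshold
   (default 0.3). A locus is *called DA* when ≥ 2/3 of cells show DA with a
   directionally consistent weaker homolog and the flagged fraction beats a
   50 % null (two-proportion z-test, α = 0.05). Treatment effects are
   assessed by the same z-test on pre- vs post-treatment DA fractions
   (reduction significant at z < −2.0) and a two-tailed Welch t-test on the
   per-cell $d$ values (group means reported as Δμ). One-way ANOVA and
   Pearson correlation are provided for the auxiliary comparisons.
4. **3D-SIM volumetrics** — from super-resolution z-stacks (17 optical
   sections, 0.13 μm step), per-homolog probe **depth** (sections with
   segmented signal × step) and **volume** (voxels × voxel size), with raw
   and normalized inter-homolog differences.

Because no public image data accompany this method, the package ships a
first-class **synthetic scene generator**: paired Gaussian probe spots with
controllable true $d$, Poisson(-Gaussian) noise, and 3D stacks with
controllable axial extent — every downstream stage is tested against this
known ground truth.

## Worked example

```python
from dafish.pipeline import RunConfig, run_pipeline
from dafish.synthetic import CohortSpec

cfg = RunConfig(
    locus_id="demo-locus",
    pre=CohortSpec(n_cells=40, fraction_da_cells=0.85, seed=11),   # untreated
    post=CohortSpec(n_cells=40, fraction_da_cells=0.15, seed=12),  # treated
)
result = run_pipeline(cfg, outdir="demo")
print(open("demo/report.txt").read())
```

prints

```
DA pipeline report — locus demo-locus

pre: 33/40 cells flagged (82.5 %), weaker homolog A, z = 3.07, p = 0.00211 -> DA
post: 3/40 cells flagged (7.5 %), weaker homolog A, z = -4.20, p = 2.68e-05 -> no DA
pre vs post: z = -6.74 (significant reduction), delta_mu 0.515 -> 0.135, Welch t = 8.41, p = 8.73e-12
```

Reading this: 82.5 % of untreated cells showed DA (above the two-thirds
criterion, dotted-line threshold in the ladder-plot convention), always with
homolog A weaker, so the locus is called DA. After treatment only 7.5 % of
cells show DA; the pre/post two-proportion z of −6.74 < −2.0 marks a
significant reduction, and the mean normalized difference Δμ drops from
0.515 to 0.135 (Welch t, p ≈ 9e−12). The `demo/` directory holds the truth
tables, per-cell measurements, QC log and locus results as TSV.

The same stages are available from the shell:

```sh
dafish init-config -o config.json
dafish run -c config.json -o out/
dafish simulate | segment | quantify | call-da | volumetrics | report ...
```

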