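# sbpquant

Automated morphometric and graph-topological quantification of the
**corneal subbasal nerve plexus (SBP)** from pre-segmented in-vivo
confocal laser-scanning microscopy images, with the cohort statistics
used to separate diabetic-neuropathy patients from healthy controls.

The SBP is the dense layer of thin nerve fibres between the corneal
basal epithelium and Bowman's membrane. Its rarefaction is an early,
non-invasively observable marker of diabetic peripheral neuropathy.
`sbpquant` takes binary masks in which fibre pixels have already been
traced (384×384 px over a 400×400 µm field by default) and computes a
standard parameter vector per image:

- **before skeletonisation** — component pixels, component ratio (%),
  number of connected components (individual fibre networks), and a
  spatial-homogeneity score (variance of per-tile coverage fractions);
- **after skeletonisation** — the mask is thinned to its one-pixel
  medial axis and converted to a graph of typed nodes (branch points,
  true nerve endings, border-crossing *connectivity points*) joined by
  traced fibre segments. From the graph: skeleton pixels, single nerve
  fibres, fibres per component, total and mean fibre length (chain
  code: 1 pitch per orthogonal step, √2 per diagonal), nerve fibre
  density ρ = L_total / A (µm of fibre per µm²; a healthy plexus is
  ~0.02, a severely rarefied one ~0.006), branch / endpoint /
  connectivity counts.

Extensive quantities can be normalised to a reference area of 1 mm²
(×6.25 for the default 0.16 mm² field). A statistics layer provides
descriptive summaries, a Kolmogorov–Smirnov-driven choice between
Welch's t-test and Mann–Whitney U, Welch tests from printed summary
tables, and stepwise linear discriminant analysis driven by Wilks' Λ.

Because clinical confocal images are generally not redistributable,
the package ships a **phantom generator**: seeded binary masks of
smooth, sinusoidally tortuous fibre curves with exact analytic ground
truth (length, branches, endpoints, border crossings), used throughout
the test-suite to validate the measurement chain.

## Worked example

```bash
python examples/quantify_phantom.py
```

```
field: 384x384 px, 0.16 mm^2
component pixels     :   8390
component ratio      :   5.69 %
components           :      8
skeleton pixels      :   2717
single nerve fibres  :     12   (truth 12)
branches             :      2   (truth 2)
endpoints            :      4   (truth 4)
connectivity points  :     14   (truth 14)
total fibre length   :   2938.3 µm (truth 2856.8)
fibre density        :  0.01836 µm/µm²

length recovery error: 2.85 %
```

Every topological count matches the generator's ground truth exactly;
the total length is recovered to within the chain-code measurement
bias of a few percent. The density 0.0184 µm/µm² is typical of a
healthy plexus. `examples/cohort_statistics.py` and
`examples/discriminant_classification.py` show the statistics layer on
simulated cohorts; the command-line interface (`sbpquant quantify`,
`sbpquant simulate`, `sbpquant compare`) batches the same operations
over directories of images.

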