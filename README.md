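# metalloprof

Fe/Cu metalloprotein fold-family inventories from meta-omic reads, with
oxygen-minimum-zone (OMZ) geochemistry statistics.

Iron and copper are the limiting cofactors of the enzymes that run
marine oxygen and nitrogen cycling — cytochrome c oxidase, nitrate and
nitrite reductases, nitrous oxide reductase. In OMZ water columns,
dissolved Fe rises sharply at the oxic–anoxic transition while
dissolved Cu stays nearly constant, so the seawater Fe:Cu molar ratio
tracks oxygen loss, and the community's inventory of Fe- vs Cu-binding
proteins is expected to shift with it. `metalloprof` is a desk-scale,
fully testable pipeline for that analysis:

1. **Reference building** — parse a SCOP-style structural hierarchy
   (integer sunids, dotted sccs labels such as `b.6.1.3`), recursively
   expand curated Fe/Cu family seed lists into domain sequences, and
   write labeled reference FASTAs. The Fe regulatory protein aconitase
   (`c.83.1.1`) is excluded by default to keep the inventory catalytic.
2. **Search** — quality-filter/merge reads, translate six frames, and
   align locally (BLOSUM62, affine gaps, Karlin–Altschul bit scores;
   hits kept at bit ≥ 50 and E ≤ 0.1), or import external 12-column
   tabular hits. Protein FASTA input ("genome mode") skips translation.
3. **Inventory** — fractional top-hit weights (k equal-best hits get
   1/k each), splitting of multidomain cupredoxins into NirK vs
   multicopper oxidases by description rules, clustering of families
   below 4% of the total into "others", and normalization per 100,000
   protein-coding sequences.
4. **Taxonomy** — MEGAN-style lowest-common-ancestor assignment
   (min score 50, max expected 0.01, top percent 10) with phylum
   rollups.
5. **Geochemistry & statistics** — five-zone O2/depth classification,
   OLS of Fe:Cu on O2 with the zero-oxygen (maximum-ratio) prediction,
   Spearman screens (exact permutation p below n = 10), rarefaction by
   repeated subsampling, and partial canonical correspondence analysis.
6. **Synthetic data** — seeded generators for every input, so the whole
   pipeline runs and is verified offline.

See `docs/methods.md` for models, parameter defaults, and limitations.

## Worked example

Simulate a fixture (hierarchy, 500 reads, taxonomy, geochemistry) and
run the full pipeline:

```sh
metalloprof simulate --out demo/fixture --seed 7 --n-reads 500
metalloprof run --input-dir demo/fixture --out demo/run --seed 7
```

`demo/run/inventory_Cu.tsv` — the per-sample Cu inventory, with the
cupredoxin family split into NirK and MCO and counts normalized per
100,000 protein-coding sequences (the denominator here is the
fixture's 50,000, so per-100k = 2 × weighted count):

```
label	metal	weighted_count	per_100k
b.6.1.1	Cu	53.000000	106.000000
b.6.1.2	Cu	47.000000	94.000000
b.6.1.3/MCO	Cu	30.000000	60.000000
b.6.1.3/nirK	Cu	29.000000	58.000000
b.69.3.1	Cu	41.000000	82.000000
total	Cu	200.000000	400.000000
```

`demo/run/correlations.tsv` (O2 rows) — the planted gradient is
recovered: Fe families correlate negatively with O2 and the
cytochrome-c-oxidase-like Cu label positively, with Benjamini–Hochberg
q-values alongside raw p:

```
 x           y       rho        p  n        q
o2 Fe:c.81.1.1 -0.760714 0.000991 15 0.003649
o2 Fe:f.24.1.1 -0.828571 0.000135 15 0.001041
o2 Fe:a.93.1.3 -0.876567 0.000018 15 0.000433
o2 Fe:d.15.4.2 -0.857143 0.000044 15 0.000711
o2 Cu:f.24.1.1  0.899017 0.000005 15 0.000249
o2  Cu:b.6.1.1 -0.073411 0.794860 15 0.887286
```

`demo/run/phylum_fractions.csv` shows the metal-taxon contrast planted
in the fixture (Fe-family reads from Planctomycetes, Cu from
Thaumarchaeota), and `demo/run/cca_summary.json` reports the partial
CCA decomposition (total inertia 0.1039, of which 0.0267 is explained
by the geochemical constraints after removing depth/temperature).
Reruns with the same config are byte-identical; `manifest.json` lists
every output with a checksum.

In library form the same stages are `reference_db.build_metal_reference`,
`search.search_reads`, `inventory.profile_sample`, `taxonomy.assign_lca`,
and `geochem_stats.{classify_zone, fit_fe_cu_vs_o2, spearman_screen,
rarefy_matrix, partial_cca}`.

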