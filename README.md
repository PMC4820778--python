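# villimorph

3D morphometry of isolated peripheral villous trees of the human placenta.

The villous tree is the branched exchange structure at the feto-maternal
border. In intrauterine growth retardation (IUGR), its most peripheral
branches remodel in ways that 2D histology cannot resolve: terminal branching
angles shift upward, and a subgroup of clinically normal placentas develops
conspicuously tortuous branches just behind the terminal tips — a candidate
morphological correlate of *compensated* ischemic placental disease.
`villimorph` is a reusable, tested pipeline for exactly this kind of
analysis: it ingests skeletonized 3D tracings of villous trees (SWC files
with micrometer coordinates and radii), quantifies each branch, aggregates
per placenta, classifies tortuosity subgroups and runs the full group
comparison battery. It is written for placental morphologists and for anyone
analyzing traced tree skeletons by distance-to-terminal topology.

## The measurements

Branches (point chains between branching nodes and/or terminal ends) are
classified by **terminal distance order**: bT0 branches end at a terminal
end, bT1 are one node away from the nearest terminal end, bT2 two nodes
away; in general `order(b) = 1 + min over children c of order(c)`. The
proximal cut end (root of the tracing) never counts as a terminal end.
Per branch, the package measures:

- **planar branching angle (mpa)** — the change of direction relative to the
  parent branch, in degrees in [0, 180]; directions are endpoint-to-endpoint
  chords (a local-tangent variant is available). The root branch has no
  previous branch, so its angle is absent.
- **tortuosity (mt)** — centerline path length divided by the straight
  distance between the branch's own endpoints; a straight branch has
  tortuosity exactly 1.
- **length (ml), surface area (msa), volume (mv)** — from the frustum model:
  every segment between consecutive center points is a truncated cone with
  end radii d/2; lateral surfaces only.

Per placenta and order, the unweighted arithmetic mean of each measure is
formed ("one value per investigated placenta"). Clinically normal placentas
with mean bT1 tortuosity above 1.2 are labeled **HT-normal**, below it
**LT-normal**; IUGR, HT-normal and LT-normal are then compared by
Kruskal-Wallis with Dunn's pairwise tests (Bonferroni-adjusted by default),
and the per-placenta mean bT0 angles are summarized per group by rose
histograms, wrapped-kernel-density modes and Hartigan's dip test with a
seeded Monte-Carlo uniform-null p-value. All of these statistics are
implemented from first principles in `villimorph.cohort_stats` and verified
against independent oracles in the test suite.

Because no traced placental cohort is publicly deposited, the package ships
a synthetic-data module that generates SWC cohorts with known ground truth:
40 IUGR specimens with bimodal terminal angles (58/76 deg), 36 LT-normal
(52/64 deg) and 14 HT-normal (unimodal 67 deg) specimens, bT1 tortuosity
regimes separated at the 1.2 cutoff, and group-specific probabilities of
trees too small to contain bT2 branches.

## Worked example

```sh
villimorph simulate --seed 0 --out cohort        # 90 SWC files + manifest
villimorph study --manifest cohort/manifest.csv --out study --seed 0
```

prints

```
specimens by subgroup: {'HT-normal': 14, 'IUGR': 40, 'LT-normal': 36}
report: study/report.json
```

and the report contains, among the full battery (`tests`, `angular_mpa_bT0`,
`subgroups`, provenance digests):

```
KW mt_bT1 H=35.17 p=2.30e-08
 dunn ['HT-normal', 'IUGR']      z=5.44 p_adj=1.61e-07 ***
 dunn ['HT-normal', 'LT-normal'] z=5.59 p_adj=6.93e-08 ***
 dunn ['IUGR', 'LT-normal']      z=0.31 p_adj=1
IUGR       modes: [58.0, 75.0]  dip=0.1183 p=0.000
LT-normal  modes: [51.0, 64.0]  dip=0.0957 p=0.006
HT-normal  modes: [67.0]        dip=0.1083 p=0.132
```

Reading this: the pipeline rediscovered the 14 high-tortuosity normals from
the manifest's plain "normal" labels; preterminal tortuosity separates
HT-normal from both IUGR and LT-normal but not IUGR from LT-normal; the
IUGR and LT-normal terminal-angle distributions are bimodal (significant
dip, two detected modes near the generating 58/76 and 52/64 degrees) while
the HT-normal distribution has a single mode at 67 degrees. `study/` also
holds per-branch and per-specimen CSV tables and rose-diagram/scatter
figures.

Other subcommands: `villimorph measure TREE.swc` (one tree to a metrics
CSV) and `villimorph validate TREE.swc` (structural diagnostics). The same
functionality is available as a library (`villimorph.run_study`,
`villimorph.measure_tree`, ...).

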