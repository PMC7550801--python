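# kinasedyn

Analysis toolkit for multi-replica MD trajectories of kinases, built
around centre-of-geometry (cog) metrics:

- **structures_io** — PDB / multi-model PDB / DCD / XTC readers, a typed
  topology (author residue numbering, altloc resolved by occupancy),
  interval + atom-subset selections.
- **geometry_metrics** — cog apex angles (e.g. activation-segment-helix
  vs αC-helix with the hinge region as vertex), interval-shift
  robustness checks, cog–cog distances (nm), Kabsch superposition, RMSD,
  replica-aggregated per-residue RMSF, equilibration exclusion and
  1.5·IQR boxplot summaries.
- **ensemble_pca** — one backbone PCA fitted across all systems (pooled
  mean fit, 1/N covariance, no mass weighting), per-system score
  projection, PC retention by variance fraction (> 9 % by default).
- **contact_analysis** — salt bridges (4.0 Å), hydrophobic side-chain
  contacts (2.5 Å, hydrogens included), hydrogen bonds, π–π stacking,
  single-water bridges; frequency tables filtered by cross-system spread
  and the replicas-above-30 % heatmap count.
- **secondary_structure** — DSSP-style H-bond-energy assignment
  ({helix, strand, other}) with amide-H reconstruction, and %SSE per
  interval.
- **synthetic_data** — seeded generators with exact ground truth: an
  ideal-geometry backbone builder (NeRF), a hinged toy kinase driven by
  an Ornstein–Uhlenbeck angle process, a C2 toy dimer with scripted
  twist/translation schedules and bridging pseudo-waters, a Bernoulli
  contact pair, and isotropic-jitter replicas (RMSF → σ√3).
- **pipeline_cli** — YAML-config orchestration of the full battery with
  a run manifest and caching, plus the `kinasedyn` command line.

## Reference crystal structure

A few tests and both acceptance targets evaluate the reference angles
(14.9° / 17.9° for subunits A and B) on the public crystal dimer, PDB
entry **3alo**. The file is *not* redistributed here; place the
PDB-format entry at `src/kinasedyn/data/3alo.pdb` (or point
`KINASEDYN_PDB_DIR` at a directory containing `3alo.pdb`). When the
network is reachable, `scripts/acceptance.py` downloads it
automatically; offline without the file, the related tests fail with an
explicit message and the acceptance targets are omitted.

## CLI

```sh
kinasedyn angle    --topology traj.pdb --dt-ns 1.0 --exclude-ns 250 \
                   --ray-a A:250-264 --vertex A:179-182 --ray-b A:139-154 \
                   --out angles.csv --summary-json box.json
kinasedyn distance --topology dimer.pdb --dt-ns 1.0 \
                   --select-a A:102-126 --select-b B:102-126 --out d.csv
kinasedyn rmsd     --topology traj.pdb --dt-ns 1.0 --select A:250-264 --out rmsd.csv
kinasedyn rmsf     --topology rep1.pdb --topology rep2.pdb --dt-ns 1.0 \
                   --select A:1-125 --out rmsf.csv
kinasedyn pca fit  --topology sys1.pdb --topology sys2.pdb --dt-ns 1.0 \
                   --select A:250-264 --out model.json
kinasedyn contacts --topology traj.pdb --dt-ns 1.0 --pairs pairs.yaml --out freq.csv
kinasedyn sse      --topology traj.pdb --dt-ns 1.0 --interval A:250-264 --out sse.csv
kinasedyn synth hinge|dimer|contact|jitter --out prefix   # ground-truth data
kinasedyn run      --config analysis.yaml                 # full battery
kinasedyn crystal-report --structure dimer.pdb
```

Long-format CSV output uses the header `system,replica,frame,time_ns,value`.
A minimal pipeline config:

```yaml
systems:
  Up:
    - {topology: up_rep1.pdb, frame_dt_ns: 1.0}
    - {topology: up_rep2.pdb, frame_dt_ns: 1.0}
exclude_ns: 250
out_dir: results/run1
```

## Notes

- Coordinates are carried in Å internally; reported distances/RMSD/RMSF
  are nm, angles are degrees.
- Frame→time mapping is mandatory metadata (`--dt-ns` or an explicit
  list); equilibration exclusion keeps frames with `time_ns >= cutoff`.
- `tests/data/` contains two small public crystal/NMR structures used as
  fixtures for the secondary-structure oracle comparison.
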