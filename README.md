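# lipidsite

Protein–lipid interaction analysis for coarse-grained membrane simulations:
contact-interval extraction, residence-time estimation from the survival
time-correlation function, and binding-site identification by residue-pair
coincidence clustering — built around the question of where and for how long
cardiolipin binds a membrane protein such as the mitochondrial ADP/ATP
carrier, embedded in a POPC/POPE/cardiolipin bilayer.

It is aimed at simulation scientists who have bead trajectories (GRO/PDB +
XTC/DCD, or the package's plain-text fixture format) and want reproducible,
tested answers to three questions:

1. **When is a lipid bound?** A lipid headgroup interacts when at least one
   of its phosphate beads lies within a cutoff (default 0.7 nm) of any
   protein bead; a whole lipid interacts when at least four of its beads do.
   Distances are minimum-image under the periodic box and smoothed by a
   centred running average (default 50 frames ≡ 60 ns at 1.2 ns spacing) to
   remove thermal on–off flicker. Maximal runs of interacting frames become
   interaction intervals; runs touching the trajectory ends are flagged
   censored.

2. **How long does it stay?** From the interval ensemble the normalised
   survival time-correlation function is built:

   σ(t) = (1/N_j) · (1/(T−t)) · Σ_j Σ_ν ρ_j(ν, ν+t),

   where ρ_j(ν, ν+t) = 1 iff lipid j interacts continuously over the whole
   window [ν, ν+t], N_j counts lipids with non-zero interaction time, and ν
   runs on a 1 ns grid. σ is normalised so σ(0) = 1 and fitted by weighted
   least squares to exp(−t/θ), or to A·exp(−t/θ₁) + B·exp(−t/θ₂) when fast
   and slow populations coexist (the long θ₂ is the reported residence
   time). Uncertainties come from resampling the lipid set 1500 times with
   replacement and refitting. The inner and outer leaflets are treated as
   separate interaction surfaces and their θ values averaged per lipid type.

3. **Where does it bind?** Per frame and per cardiolipin, the set of protein
   residues within the cutoff of either phosphate bead is recorded. The
   residue-pair metric

   d_l(res_i, res_j) = 1 − (1/N_int,l) · Σ_n Σ_t χ_{n,t}(res_i, res_j)

   (χ = 1 when one cardiolipin's phosphates touch both residues at once,
   N_int,l = all residue–cardiolipin contact events in leaflet l) is
   clustered by single linkage; cutting the dendrogram (default height
   0.995) yields binding sites, each with an occupancy timeline and its own
   residence-time fit.

A fully seed-deterministic synthetic-trajectory generator
(`lipidsite.synthetic`) plants binding sites with known Markovian on/off
kinetics in a two-leaflet 9:7:4 POPC:POPE:CDL patch around a static bead
scaffold, so every estimator is validated against ground truth.

## Worked example

Run the full pipeline on the standard synthetic benchmark (a 20 µs
effective-time trajectory, 40 lipids per leaflet, three planted
cardiolipin-selective sites on the inner leaflet with mean dwell 2 µs over
a 150 ns nonspecific background shell; takes a couple of minutes):

```bash
cat > run.yaml <<EOF
synth: {}
outdir: demo_out
n_boot: 200
EOF
lipidsite run --config run.yaml --seed 7
```

`demo_out/summary.json` then contains (abridged):

```json
"residence_by_type": {
  "CDL":  {"inner_ns": 3618.5, "outer_ns": 124.3, "overall_ns": 1871.4},
  "POPC": {"inner_ns": 165.2,  "outer_ns": 147.7, "overall_ns": 156.5},
  "POPE": {"inner_ns": 129.9,  "outer_ns": 210.6, "overall_ns": 170.2}
},
"sites": [
  {"label": "inner-1", "residues": [0, 1, 29],   "occupancy_fraction": 0.64},
  {"label": "inner-2", "residues": [9, 10, 11],  "occupancy_fraction": 0.85},
  {"label": "inner-3", "residues": [19, 20, 21], "occupancy_fraction": 0.80},
  ...
],
"site_class_residence": {
  "inner-1": {"model": "single", "residence_time_ns": 1233.2},
  "inner-2": {"model": "single", "residence_time_ns": 1148.2},
  "inner-3": {"model": "single", "residence_time_ns": 3860.9},
  "outer-1": {"model": "single", "residence_time_ns": 100.9},
  ...
}
```

Reading this: cardiolipin in the inner leaflet has a residence time of
~3.6 µs, more than twenty times that of POPC/POPE (~150 ns) — the planted
selectivity is recovered. Clustering finds exactly the three planted
residue triplets as inner-leaflet sites, each occupied 64–85% of the time
with per-site residence times on the microsecond scale, while the
outer-leaflet clusters are transient (~60–140 ns) background contacts.
CSV companions (`residence.csv`, `intervals.csv`, `occupancy.csv`,
`dmatrix_*.csv`, `sites.tsv`) carry the per-lipid and per-frame detail;
every output embeds the config hash and seed.

The same stages are available as a library
(`contact_masks` → `extract_intervals` → `survival_correlation` →
`select_fit`; `residue_contact_table` → `pair_distance_matrix` →
`cluster_sites` → `site_occupancy_timeline`) and as individual CLI
subcommands (`lipidsite synth/load/contacts/residence`).

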