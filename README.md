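# probeseq

Quantitative tools for two questions that arise when a cofactor-competitive
chemical probe is characterized in cells:

1. **How much of the target enzyme does the probe actually engage?**
   Intracellular engagement is modeled as a competitive equilibrium between
   the enzyme, its cofactor (SAM) and every co-occurring inhibitor species,
   fed by LC-MS/MS quantification of intracellular concentrations against
   internal-standard working curves, plus the surrounding assay fits
   (IC50/EC50 dose-response, thermal-shift melting temperatures,
   radiometric percent inhibition).

2. **Which cell subpopulations respond to the probe?**  A cell-cycle-aware
   scRNA-seq workflow: cells are staged (G0/G1, S, G2/M) by marker scoring
   before clustering, the cluster resolution is chosen by a combination of
   silhouette analysis, a normalized origin-entropy score and a Monte-Carlo
   Fisher exact test against the treatment arms, and each cluster is
   classified into five treatment-response categories from its
   probe/vehicle and control/vehicle frequency ratios.

The package is aimed at chemical-biology and single-cell analysts who want
these computations as tested, reusable functions rather than spreadsheet
conventions, and ships a seed-deterministic synthetic-data generator so
every stage can be exercised without access to experimental data.

## The core models

**Competitive occupancy.** For a SAM-competitive inhibitor assayed at
cofactor concentration [SAM],

    IC50 = [SAM] · Kd / Km,SAM + Kd

so a cofactor titration is linear in [SAM], with y-intercept Kd and slope
Kd/Km,SAM.  At equilibrium, with w_SAM = C_SAM/Km,SAM and w_i = C_i/Kd_i,

    apo% = 100 / (1 + w_SAM + Σ w_i),    SAM% = 100 · w_SAM / (…),
    inhibitor_i% = 100 · w_i / (…)

with all concentrations treated as free (no depletion term).

**Entropy score.**  For a clustering with cluster fractions f_i, origin
fractions f_j and within-cluster origin fractions d_ji,

    E = [ −Σ_i f_i Σ_j d_ji ln d_ji ] / [ −Σ_j f_j ln f_j ]  ∈ [0, 1]

E = 0 when every cluster is origin-pure, E = 1 when all cells share one
cluster.  The cluster number is selected by taking the silhouette-optimal
cluster count k\*, and within [k\*, 3k\*] picking the smallest count that
minimizes the mean Monte-Carlo Fisher p over 150-cell downsampling repeats.

**Population shifts.**  Each cluster's control/vehicle ratio r_b and
probe/vehicle ratio r_a place it into one of: commonly resistant
(both in (0.8, 1.2)), commonly emerging (both ≥ 1.2), commonly depleted
(both ≤ 0.8, |r_b − r_a| < 0.15), differentially depleted (either < 0.8,
|r_b − r_a| > 0.15), differentially emerging (either > 1.2).

## Worked example

Occupancy of the target by a SAM cofactor at its measured intracellular
concentration (89 µM against Km,SAM = 0.25 µM), then in competition with
three accumulated inhibitor species:

```sh
$ probeseq occupancy --sam 89 --kd-sam 0.25
{
  "apo_pct": 0.2801120448179272,
  "sam_pct": 99.71988795518207,
  "inhibitor_pct": {}
}

$ probeseq occupancy --sam 89 --kd-sam 0.25 \
    --inhibitor "2a:100:0.017" --inhibitor "5a:10:0.009" --inhibitor "6a:5:0.28"
{
  "apo_pct": 0.013571612495108644,
  "sam_pct": 4.831494048258677,
  "inhibitor_pct": {
    "2a": 79.83301467710966,
    "5a": 15.079569439009603,
    "6a": 0.24235022312694002
  }
}
```

Under native conditions the cofactor holds >99.5% of the enzyme with <0.5%
apo; once the inhibitor species accumulate (each `NAME:CONC:KD` in µM), the
combined inhibitor occupancy reaches ~95%, displacing the cofactor.

The same computations are available as library calls
(`probeseq.occupancy.occupancy`, `probeseq.resolution.entropy_score`, …),
and `probeseq pipeline --seed 1 --outdir run/` executes the full synthetic
three-arm scRNA-seq analysis, writing per-stage resolution scans, shift
tables and marker rankings.

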