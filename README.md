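# spermfx

Functional sperm-quality analytics for paired separation-method studies.

Fertility labs compare sperm-selection procedures — classically
density-gradient centrifugation (DGC) against newer devices such as a
membrane-filter chamber (CA0) that selects cells able to self-propel through
micropores — on the *same* split semen sample. Beyond counts and motility,
functional readouts matter: the resting membrane potential (Em) of the
selected population and the magnitude and speed of the progesterone-induced
Ca²⁺ transient both correlate with fertilizing ability. `spermfx` implements
the complete quantitative side of such a study, for lab scientists and
embryologists who have the raw instrument exports and want the numbers:

* **Membrane potential** (`spermfx.em_calibration`) — resting Em of a
  dye-loaded population from a DiSC₃(5) valinomycin/K⁺-step calibration
  trace. Each stepped external K⁺ clamps the population at the Nernst
  potential E = (RT/F)·ln([K⁺]ₒ/[K⁺]ᵢ); fluorescence is regressed on these
  theoretical potentials and inverted at the pre-valinomycin fluorescence.
* **Ca²⁺ kinetics** (`spermfx.calcium_kinetics`) — ΔP4 (fold increment of
  the progesterone-induced peak over basal, on the Mn²⁺-zeroed scale), τ-up
  and τ-down (half-times of rise and recovery) from Fluo-3 traces anchored
  by ionomycin and Mn²⁺ additions.
* **CASA kinematics** (`spermfx.motility_kinematics`) — VCL, VSL, VAP and
  STR = 100·VSL/VAP per tracked cell; velocity classes at <10 / 10–35 /
  >35 µm·s⁻¹ and motility classes (progressive STR > 80%, immotile,
  non-progressive between).
* **Outcome statistics** (`spermfx.outcome_stats`) — fertilization-rate
  accounting (2PN+2PB zygotes over inseminated MII oocytes; triploids stay
  in the denominator), median ± MAD summaries (MAD unscaled), and the
  two-sided Wilcoxon signed-rank test with an exact sign-enumeration
  p-value up to n = 20 non-zero differences.
* **Synthetic data** (`spermfx.synthetic_data`, `spermfx.study`) — every
  input above can be generated with known ground truth at the study's own
  conditions, so the whole pipeline is exercisable and testable with no
  external data.

The repository is organised as an analysis project: the numbered scripts
under `analysis/` (simulate → membrane potential → Ca²⁺ → motility → paired
report) are thin narrative drivers over the library in `src/spermfx`, and
write their tables under `results/`.

## Worked example

The one-command demo generates a full synthetic paired study (18 variables,
Nz and Tz cohorts), re-estimates every membrane potential and Ca²⁺ transient
from generated traces, and prints the paired report:

```sh
spermfx demo --seed 42 --out results/demo
```

```
sample_class                variable  n_pairs  dgc_median  dgc_mad  ca0_median  ca0_mad  p_two_sided significance
          Nz             sperm_count       12          36     8.13          52      9.5        0.021      P<=0.05
          Tz             sperm_count       36         4.8    0.742         9.2     2.25     1.91e-07     P<=0.001
          Nz         pct_progressive        9          79     2.94          88     3.35       0.0195      P<=0.05
          Tz  fertilization_rate_ivf       72        71.4     27.3        66.6     20.4     0.000378     P<=0.001
          Nz              resting_em       11       -48.7     8.44       -43.8     12.4       0.0537           NS
          Tz              resting_em       22         -79     6.02       -66.8     8.29     0.000166     P<=0.001
          Nz                delta_p4        9         1.9    0.159         1.11   0.0988      0.00391      P<=0.01
          Nz                  tau_up        9        3.23     1.11         2.72    0.348         0.25           NS
          ...
```

Each row is one paired variable: the median ± MAD of the DGC and CA0 arms
over the per-subject pairs, the exact (or, above n = 20, normal-approximate)
two-sided Wilcoxon signed-rank p-value, and its significance tier. The Em
and Ca²⁺ medians are *measured* — every subject's value was regenerated as a
noisy fluorescence trace and re-estimated — which is why they sit within a
percent or two of the generating medians rather than exactly on them. The
run is byte-identical for a fixed seed, and `results/demo/manifest.json`
records the seed, configuration hash and per-file checksums.

Single-variable commands work on plain text trace/track files (see
`spermfx --help`): `simulate`, `em`, `ca`, `casa`, `report`.

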