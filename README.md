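# stairmwi — STAIR-EPI myelin water imaging toolkit

Myelin water — the water trapped between the lipid bilayers of the myelin
sheath — has much shorter relaxation times (T1 ≈ 220 ms, T2\* ≈ 10 ms) than
intra/extracellular water (T1 ≈ 600–2000 ms). The STAIR preparation
(**S**hort-**T**R **A**diabatic **I**nversion **R**ecovery) exploits this: an
adiabatic inversion pulse combined with a short repetition time and an
optimised inversion time suppresses the whole long-T1 band at once, leaving an
image dominated by myelin water. Dividing it by a proton-density-weighted
reference yields a voxel-wise **apparent myelin water fraction (aMWF)** map —
a demyelination biomarker, e.g. for multiple sclerosis (MS) lesions and
normal-appearing white matter (NAWM).

This package is for quantitative-MRI researchers who want to design, simulate
and validate such protocols without scanner access: it implements the signal
model, the protocol optimisation, a Bloch simulator for the inversion pulse,
a synthetic digital brain phantom, the aMWF estimator, and the group
statistics used to compare NWM / NAWM / lesion cohorts.

## Model

Steady-state STAIR signal of a pool with relaxation times $T_1, T_2^*$ and
inversion efficiency $Q$ (−1 = full inversion, +1 = untouched):

$$S_\mathrm{STAIR} = M_0\left(1 - Q e^{-TR/T_1} - (1-Q)e^{-TI/T_1}\right)e^{-TE/T_2^*}$$

The optimal TI minimises the mean-squared residual of fully inverted
($Q=-1$) pools over $T_1 \in [600, 2000]$ ms; at TR = 250 ms this gives
TI = 117 ms with a worst-case residual of 1.3 % of $M_0$. Because the
8.64 ms adiabatic full-passage pulse is long compared with the myelin-water
$T_2^*$, its inversion is incomplete for myelin water: Bloch simulation with
relaxation gives $Q_\mathrm{MW} \approx -0.75$ (vs ≈ −1 for long-T2 water).
The aMWF is then a scaled image ratio against the proton-density (PD)
reference $S_\mathrm{PD} = M_0^\mathrm{total} e^{-TE/T_{2,\mathrm{total}}^*}$:

$$\mathrm{aMWF} = \frac{M_0^\mathrm{MW}}{M_0^\mathrm{total}}
 = k\,\frac{S_\mathrm{STAIR}}{S_\mathrm{PD}},\qquad
 k = \frac{e^{-TE/T_{2,\mathrm{total}}^*}}
   {\left(1 - Q_\mathrm{MW} e^{-TR/T_{1,\mathrm{MW}}} -
     (1-Q_\mathrm{MW}) e^{-TI/T_{1,\mathrm{MW}}}\right) e^{-TE/T_{2,\mathrm{MW}}^*}}$$

With the default protocol (TR/TI/TE = 250/117/5.5 ms) and constants
($T_{1,\mathrm{MW}}$ = 220 ms, $T_{2,\mathrm{MW}}^*$ = 10 ms,
$T_{2,\mathrm{total}}^*$ = 60 ms, $Q_\mathrm{MW}$ = −0.75), k ≈ 7.44.

## Worked example

Protocol design from the command line:

```
$ stairmwi optimize-ti --tr 250
TI = 116.73 ms (protocol: 117 ms)
max |residual| over T1 in [600, 2000] ms: 1.282% of M0
```

i.e. a single TI of 117 ms keeps every long-T1 species in the 600–2000 ms
band below 1.3 % of its equilibrium magnetization.

Simulating a study (7 healthy volunteers with normal white matter,
7 patients with NAWM plus 9 lesions each; noisy phantom volumes; 4 Monte
Carlo cohort replicates) and comparing groups:

```python
from stairmwi import run_study

obs, report = run_study(master_seed=1, n_replicates=4)
print(report.group_table().to_string(index=False))
df1, df2 = report.anova_df
print(f"ANOVA: F({df1}, {df2}) = {report.anova_f:.1f}, p = {report.anova_p:.3g}")
```

```
 group   n  mean_pct   sd_pct  ci95_lo_pct  ci95_hi_pct
   NWM 224 10.602305 0.984451    10.472682    10.731928
  NAWM 224  8.987323 1.453917     8.795885     9.178760
lesion 252  3.927938 1.086052     3.793198     4.062678
ANOVA: F(2, 697) = 2070.4, p = 5.81e-294
```

The pooled white-matter ROI means recover the simulated ground truths
(9.9 % NWM, 8.5 % NAWM, 3.6 % lesion) up to between-subject sampling and a
small Rician magnitude bias, and every Games–Howell pairwise comparison is
significant — lesions and NAWM are clearly separable from normal white
matter at this SNR.

Other entry points: `stairmwi bloch-q` (inversion-efficiency-vs-T2 table),
`stairmwi simulate-phantom` (NIfTI volumes + ground-truth CSV),
`stairmwi compute-amwf`, `stairmwi roi-stats`, `stairmwi group-stats`.

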