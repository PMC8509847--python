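# fbandnet

Frequency-resolved analysis of resting-state functional brain networks for
paired (before/after treatment) designs.

Resting-state fMRI connectivity is frequency dependent: disease- and
treatment-related changes concentrate in specific bands of the slow BOLD
fluctuations. `fbandnet` implements the full analysis chain for asking, on a
small paired cohort, *which connections and which topological properties of
the brain network changed after treatment, and in which frequency band* —
together with a synthetic-cohort generator that makes every step of the
chain testable against planted ground truth.

## The method

Given per-subject, per-session ROI time series (by default the 76
cortical/subcortical regions of the Desikan–Killiany parcellation, 180
volumes at TR = 2 s):

1. **Motion scrubbing.** A volume is censored when DVARS > 8 and/or
   framewise displacement > 0.5, together with the previous volume and the
   two following; censored volumes are flagged and excluded at the
   correlation step (never deleted before filtering, which needs a
   contiguous series). Nuisance series (CSF/white matter) are regressed out
   at the ROI level.
2. **Wavelet band decomposition.** A 4-level stationary (undecimated,
   translation-invariant) discrete wavelet transform with the `db4` wavelet
   splits each region's series into detail bands ≈ 0.12–0.25, 0.06–0.12,
   0.03–0.06 and 0.015–0.03 Hz (level *j* covers (f_N/2^j, f_N/2^{j−1}),
   f_N = 1/(2·TR)).
3. **Connectivity.** Per band and session, the Pearson correlation w_ij of
   the band-limited series gives a 76 × 76 matrix with 2850 unique
   connections.
4. **Graph topology.** The strongest positive correlations are kept at
   densities 10–50% (negative correlations are never admitted). On each
   binary graph: clustering C_i, harmonic characteristic path length
   L_net = n(n−1)/Σ_{i≠j} d_ij^{−1}, global/local efficiency, degree,
   strength, betweenness centrality, participation coefficient
   y_i = 1 − Σ_m (k_i(m)/k_i)², and within-module degree z-score. C_net and
   L_net are normalized by degree-preserving rewired null networks:
   C_norm = C_net/C_rand, L_norm = L_net/L_rand, and smallworldness
   σ = C_norm/L_norm (> 1 for small-world organization). Density curves are
   summarized by their AUC (the mean over the uniform grid).
5. **Paired inference.** Each feature's change D (post − pre) is tested by
   the exhaustive sign-flip permutation test: with n = 12 subjects all 2^12
   = 4096 sign assignments are enumerated and p is the tail probability of
   the permuted mean D′ beyond D in the direction of sign(D), so every p is
   a multiple of 2^−12 = 0.0002441. Effect sizes are Cohen's d with pooled
   SD; power is that of the two-sided one-sample t-test on the changes via
   the noncentral-t distribution. Bonferroni thresholds are 0.05/76 ≈
   0.00066 (regions) and 0.05/2850 ≈ 1.75 × 10⁻⁵ (connections), and
   Benjamini–Hochberg FDR at α = 0.05 extracts the significantly changed
   subnetwork per band, characterized by within-subnetwork nodal degree.
6. **Clinical association.** Changes in the depression score (post − pre,
   negative = improvement) are regressed on network features with age, sex
   and IQ partialed out (OLS; exploratory, uncorrected).

The synthetic-cohort generator produces paired sessions whose band-limited
signals carry user-specified per-band correlation structure (with planted
treatment effects on chosen edges), band-limited with the same wavelet
filters as the analysis and leakage-compensated so that measured band
correlations match the requested ground truth.

## Worked example

```python
import numpy as np
import fbandnet as fb

# a paired cohort with a planted connectivity decrease in the 0.12-0.25 Hz band
spec = fb.CohortSpec(
    n_subjects=12, n_regions=76, n_volumes=180, tr=2.0,
    effect_edges=[fb.EffectEdge(i, i + 36, band=1, delta_r=-0.3) for i in range(10)],
    seed=7,
)
cohort = fb.generate_cohort(spec)

# band-limited connectivity for one session
bands = fb.sdwt_decompose(cohort.pre[0])
print("band 1 range (Hz):", bands.band_ranges[0])
conn = fb.band_connectivity(bands, band_index=1)
print("unique connections:", len(conn.upper_triangle()))

# small-world topology of the 10%-density core network
core = fb.threshold_by_density(conn, 0.10)
m = fb.small_world_metrics(core, n_rand=100, seed=0)
print(f"core network: C_norm={m.c_norm:.2f}, L_norm={m.l_norm:.2f}, sigma={m.sigma:.2f}")

# exhaustive paired sign-flip test on one planted edge
pre = np.array([fb.band_connectivity(fb.sdwt_decompose(t), 1).values[0, 36] for t in cohort.pre])
post = np.array([fb.band_connectivity(fb.sdwt_decompose(t), 1).values[0, 36] for t in cohort.post])
res = fb.sign_permutation_test(fb.PairedSample(pre, post))
print(f"planted edge: D={res.observed_d:+.3f}, p={res.p:.7f} "
      f"({res.n_realizations} assignments), d={res.effect_size_d:+.2f}, power={res.power:.2f}")
```

Output:

```
band 1 range (Hz): (0.125, 0.25)
unique connections: 2850
core network: C_norm=7.23, L_norm=3.73, sigma=1.94
planted edge: D=-0.301, p=0.0002441 (4096 assignments), d=-3.45, power=1.00
```

The sparse core network is far more clustered than its degree-matched
random references (C_norm ≫ 1) and small world (σ > 1); the planted
connectivity decrease is recovered at the permutation floor p = 2^−12 with
a large negative effect size.

## The analysis

`analysis/` contains the numbered end-to-end study on a simulated cohort
(12 subjects, 76 regions, paired sessions, twenty planted band-1
connectivity decreases):

1. `01_simulate_cohort.py` — generate and write the cohort + clinical scores
2. `02_band_connectivity.py` — wavelet bands and per-band connectivity
3. `03_network_topology.py` — density-thresholded topology, normalized
   small-world curves, AUCs
4. `04_group_inference.py` — permutation tests, Bonferroni, FDR subnetworks
5. `05_clinical_association.py` — covariate-partialed clinical regressions

Each writes its tables under `results/` and prints what it found.

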