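# prolylnmr

Quantitative NMR analysis of peptidyl-prolyl *cis/trans* isomerization and
WW-domain binding, built around three measurements made on a
phosphorylated Ser-Pro peptide motif and its phosphomimetic mutant in the
presence of the prolyl isomerase PIN1:

1. **ROESY/EXSY build-up fitting.** Exchange between the *cis* and *trans*
   conformers during the ROESY mixing time produces cross peaks whose
   build-up encodes the catalyzed exchange rates. The longitudinal two-site
   kinetic matrix

   ```
   A = [[k_ct + R2c,  -k_tc],
        [-k_ct,  k_tc + R2t]]
   ```

   with eigenvalues λ₁,₂ = ½[(a₁₁+a₂₂) ± √((a₁₁−a₂₂)² + 4 k_ct k_tc)]
   gives closed-form biexponential diagonal (I_cc, I_tt) and cross-peak
   (I_ct, I_tc) intensities versus mixing time t_m. Fitting the
   cross/diagonal ratios r_ct = I_ct/I_cc and r_tc = I_tc/I_tt — in which
   the initial intensities and the common relaxation cancel — recovers
   (k_ct, k_tc, ΔR₂), hence k_ex = k_ct + k_tc and the detailed-balance
   population ratio K_isom = k_ct/k_tc, which can be cross-checked against
   an independent TOCSY trans/cis intensity ratio.

2. **Fast-exchange CSP titrations.** A reverse titration (constant ¹⁵N
   protein, ligand serially halved) perturbs amide peaks by
   Δδ = Δδ_max·[PL]/P with the ligand-depleting quadratic isotherm
   [PL] = ((P+L+K_D) − √((P+L+K_D)² − 4PL))/2. Per-peak two-parameter fits
   of the composite CSP √(ΔδH² + (0.14·ΔδN)²) are aggregated as
   mean ± s.d. to give the apparent K_D.

3. **Ensemble structure QC.** Kabsch superposition and backbone (N, CA, C)
   RMSD over residue ranges of a multi-model NMR ensemble, with "to mean"
   and "pairwise" conventions.

A seeded synthetic-data module generates all inputs with known ground
truth, so every fitting stage is testable without downloads.

## Worked example

Generate the synthetic study datasets and fit them (numbered drivers under
`analysis/` write their tables to `results/`):

```sh
python analysis/01_simulate_datasets.py
python analysis/02_fit_exchange_rates.py
python analysis/03_fit_titration_kd.py
python analysis/04_ensemble_precision.py
```

which prints, for the simulated datasets at 1% intensity noise:

```
pS110: k_ct 26.196 (truth 26.5), k_tc 2.489 (truth 2.48), k_ex 28.685 (truth 28.98); rates-vs-TOCSY discrepancy 2.6% (pass)
S110E: k_ct 0.718 (truth 0.73), k_tc 0.110 (truth 0.11), k_ex 0.828 (truth 0.84); rates-vs-TOCSY discrepancy 5.7% (pass)
apparent K_D = 61.6 +/- 2.7 uM (mean +/- s.d., n=10); truth 60.7 uM
synthetic 20-model ensemble: mean backbone RMSD 0.202 A (expected 0.203 A)
```

The fast phosphopeptide exchange (k_ex ≈ 29 s⁻¹) and the ~35× slower
phosphomimetic exchange are both recovered within a few percent of the
generating rates; the fitted rate ratio k_ct/k_tc agrees with the
independently simulated TOCSY population ratio (detailed balance); and the
per-peak K_D fits recover the generating affinity with a spread set by the
shift noise.

The same stages are available as a CLI
(`prolylnmr simulate-roesy | fit-exchange | simulate-titration |
fit-titration | ensemble-rmsd`), e.g.

```sh
prolylnmr simulate-roesy --k-ct 26.5 --k-tc 2.48 --noise 0.01 --seed 1 \
    --table roesy.csv --out sim.json
prolylnmr fit-exchange --table roesy.csv --noise-sd 0.01 --seed 1 --out fit.json
```

`04_ensemble_precision.py` additionally accepts a multi-model PDB path and
then reports the helical-core backbone RMSD (residues 14–47 and 56–105, in
both numbering conventions) of a real deposited ensemble.

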