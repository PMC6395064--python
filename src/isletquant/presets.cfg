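# Stage/condition preset registry.
#
# One section per experimental condition.  Values tagged "reported" in the
# `source` field come from published in vivo / in vitro summary statistics
# (mean +/- SEM); standard deviations were obtained from those SEMs as
# SD = SEM * sqrt(n_mid), with n_mid the midpoint of the published range of
# replicates (embryos, islet batches or islets).  Values listed under
# `assumed` were not published and are package defaults; they are chosen to
# be physiologically plausible and are documented in docs/methods.md.
#
# Units: lengths um, times s, amplitudes dimensionless Max dF/F0 fractions
# (1.456 = 145.6%), secretion ng/ml, ensemble calcium as percent of the
# 0.5 mM-phase baseline (100 = no change).

[DEFAULT]
cell_radius = 3.5
beta_fill_frac = 0.12
sync_group_prob = 0.3
onset_delay_mean = 30.0
onset_delay_sd = 10.0
tau_rise = 8.0
tau_decay = 30.0

[wt_36hpf]
n_cells_mean = 14.5
n_cells_sd = 5.228
target_responsive_mantle = 0.0
target_responsive_core = 0.0
amp_mean_mantle = 0.534
amp_sd_mantle = 0.321
amp_mean_core = 0.534
amp_sd_core = 0.321
vessel_penetration = 0.05
source = reported: total cells 14.5+/-1.45 SEM (n~13 embryos)
assumed = amplitudes (no responsive cells at this stage), vessel_penetration, kinetics

[wt_48hpf]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 1.56
target_responsive_core = 0.0
amp_mean_mantle = 0.534
amp_sd_mantle = 0.321
amp_mean_core = 0.534
amp_sd_core = 0.321
vessel_penetration = 0.1
source = reported: total cells 21.88+/-0.95, responsive 1.56+/-0.27 (mantle-initiated), Max dF/F0 53.4%+/-8.9% (n~13 embryos)
assumed = core amplitude reuses the pooled stage value, vessel_penetration, kinetics

[wt_56hpf]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 4.5
target_responsive_core = 1.0
amp_mean_mantle = 0.931
amp_sd_mantle = 0.350
amp_mean_core = 0.931
amp_sd_core = 0.350
vessel_penetration = 0.3
source = reported: Max dF/F0 93.1%+/-9.7% (n~13 embryos); total cells as at 48 hpf
assumed = responsive-count split (only the stage trend is published), vessel_penetration, kinetics

[wt_72hpf]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 5.87
target_responsive_core = 5.51
amp_mean_mantle = 1.456
amp_sd_mantle = 0.299
amp_mean_core = 1.456
amp_sd_core = 0.299
vessel_penetration = 0.9
source = reported: responsive 11.38+/-0.49 total, 5.51+/-0.43 in the core (control), Max dF/F0 145.6%+/-8.3%
assumed = mantle target is total minus core (derived), vessel_penetration, kinetics

[cloche_72hpf]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 5.87
target_responsive_core = 1.28
amp_mean_mantle = 0.594
amp_sd_mantle = 0.174
amp_mean_core = 0.594
amp_sd_core = 0.174
vessel_penetration = 0.0
source = reported: core responsive 1.28+/-0.47, Max dF/F0 59.4%+/-7.8% (n~5 embryos); avascular mutant
assumed = mantle responsive count reuses the age-matched control value, kinetics

[bdm_60_69]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 5.87
target_responsive_core = 1.75
amp_mean_mantle = 0.731
amp_sd_mantle = 0.221
amp_mean_core = 0.731
amp_sd_core = 0.221
vessel_penetration = 0.9
source = reported: core responsive 1.75+/-0.29, Max dF/F0 73.1%+/-9.9% (n~5 embryos); circulation blocked 60-69 hpf
assumed = mantle responsive count reuses the control value, vessel_penetration (vessels present, flow blocked), kinetics

[dnzcna_72hpf]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 2.13
target_responsive_core = 2.00
amp_mean_mantle = 0.787
amp_sd_mantle = 0.154
amp_mean_core = 0.787
amp_sd_core = 0.154
vessel_penetration = 0.9
coexpression_frac = 0.758
source = reported: responsive 4.13+/-1.28 total, Max dF/F0 78.7%+/-6.9%, 75.8%+/-2.5% marker co-expression (n~5 embryos)
assumed = compartment split of the responsive total (proportional to compartment size), kinetics

[mosaic_coexpression]
n_cells_mean = 21.88
n_cells_sd = 3.425
target_responsive_mantle = 5.87
target_responsive_core = 5.51
amp_mean_mantle = 1.456
amp_sd_mantle = 0.299
amp_mean_core = 1.456
amp_sd_core = 0.299
vessel_penetration = 0.9
coexpression_frac = 0.758
source = reported: 75.8%+/-2.5% of indicator-positive cells co-express the second marker
assumed = calcium parameters reuse the 72 hpf wild-type stage

[adult]
secretion_high_mean = 7.44
secretion_high_sd = 1.402
gsi_mean = 27.29
gsi_sd = 8.705
ca_low_pct_mean = 102.2
ca_low_pct_sd = 16.65
ca_high_pct_mean = 180.0
ca_high_pct_sd = 25.0
source = reported: high-glucose secretion 7.44+/-0.53 ng/ml, GSI 27.29+/-3.29 (n~7 batches); 2.8 mM ensemble calcium 102.2%+/-7.1%
assumed = 16.7 mM ensemble calcium amplitude (not printed)

[neonatal_5.6mM]
secretion_low_mean = 1.2
secretion_low_sd = 0.4
secretion_high_mean = 2.5
secretion_high_sd = 0.8
ca_low_pct_mean = 130.3
ca_low_pct_sd = 5.39
ca_high_pct_mean = 147.5
ca_high_pct_sd = 23.92
source = reported: ensemble calcium 130.3%+/-2.3% (2.8 mM) and 147.5%+/-10.2% (16.7 mM) (n~5.5 islets)
assumed = secretion values (published only graphically)

[neonatal_5.6mM_CGA]
secretion_low_mean = 1.2
secretion_low_sd = 0.4
secretion_high_mean = 3.5
secretion_high_sd = 1.0
ca_low_pct_mean = 126.4
ca_low_pct_sd = 4.46
ca_high_pct_mean = 176.4
ca_high_pct_sd = 19.70
source = reported: ensemble calcium 126.4%+/-1.9% (2.8 mM) and 176.4%+/-8.4% (16.7 mM)
assumed = secretion values (published only graphically)

[neonatal_11mM]
secretion_high_mean = 3.0
secretion_high_sd = 1.0
gsi_mean = 8.0
gsi_sd = 3.0
ca_low_pct_mean = 95.7
ca_low_pct_sd = 24.16
ca_high_pct_mean = 181.7
ca_high_pct_sd = 22.28
source = reported: ensemble calcium 95.7%+/-10.3% (2.8 mM) and 181.7%+/-9.5% (16.7 mM)
assumed = secretion values (published only graphically)

[neonatal_11mM_CGA]
secretion_high_mean = 7.29
secretion_high_sd = 2.275
gsi_mean = 22.74
gsi_sd = 7.091
ca_low_pct_mean = 100.0
ca_low_pct_sd = 10.0
ca_high_pct_mean = 232.2
ca_high_pct_sd = 29.32
source = reported: high-glucose secretion 7.29+/-0.86 ng/ml, GSI 22.74+/-2.68; 16.7 mM ensemble calcium 232.2%+/-12.5%
assumed = 2.8 mM ensemble calcium (low-glucose transients abolished; set to baseline)
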