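# Study-condition simulation, scaled to a quick desk run: the FACS-fraction
# design (6 X1 / 4 X2 / 6 Xins + 2 depleted-WW samples), IR-dominated event
# mix, planted |dPSI| = 40 differential events, within-group noise 5 PSI.
seed: 123
n_events: 800
n_differential: 80
delta_psi: 40.0
psi_noise_sd: 5.0
depth_mean: 150.0
depth_min: 50
n_x1: 6
n_x2: 4
n_xins: 6
n_ww_depleted: 2
planted_motif: [GCUUGC, BIN_D1, 3.0]
motif_base_rate: 0.25
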