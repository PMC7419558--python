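feature,r_noisy,r_filtered,r_combined
glcm_entropy,-0.9727,-0.9006,-0.8813
glcm_homogeneity,0.9529,0.8711,0.8603
glcm_energy,0.9891,0.8434,0.8427
glcm_correlation,-0.5491,0.4853,0.6534
ngtdm_contrast,-0.9660,-0.9929,-0.9597
ngtdm_complexity,-0.9662,-0.9914,-0.9588
ngtdm_busyness,0.9756,0.9857,0.9081
ngtdm_coarseness,-0.4690,0.4719,0.653
rlm_gln,0.9787,0.9431,0.9347
rlm_rln,-0.9547,-0.8651,-0.8573
rlm_rp,-0.9581,-0.8562,-0.8508
rlm_sre,-0.9527,-0.8551,-0.8500
rlm_lre,0.9777,0.8457,0.8453
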