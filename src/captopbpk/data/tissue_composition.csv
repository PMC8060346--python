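# Tissue composition constants for the Rodgers-Rowland tissue-to-plasma
# partitioning method (acids / very weak bases / neutrals branch).
# Sources: fractional tissue volumes of extracellular water (f_ew),
# intracellular water (f_iw), neutral lipid (f_nl) and neutral phospholipid
# (f_np) and the albumin tissue:plasma ratios (albumin_ratio) are the
# published Rodgers & Rowland (2006, J Pharm Sci 95:1238-1257) composition
# table; per-tissue volume fractions of body weight (volume_frac, L/kg) are
# standard adult human organ volumes (Poulin & Theil / ICRP reference adult).
# Intracellular pH 7.0 and plasma pH 7.4 are applied by the code, not stored
# here. Version: 1 (frozen transcription; see sha256 check in study_data).
tissue,f_ew,f_iw,f_nl,f_np,albumin_ratio,volume_frac
adipose,0.135,0.017,0.853,0.0016,0.049,0.2142
bone,0.100,0.346,0.017,0.0017,0.100,0.0856
brain,0.162,0.620,0.039,0.0015,0.048,0.0200
gut,0.282,0.475,0.038,0.0125,0.158,0.0171
heart,0.320,0.456,0.014,0.0111,0.157,0.0047
kidney,0.273,0.483,0.012,0.0240,0.130,0.0044
liver,0.161,0.573,0.014,0.0240,0.086,0.0257
lung,0.336,0.446,0.022,0.0128,0.212,0.0076
muscle,0.118,0.630,0.010,0.0072,0.064,0.4000
skin,0.382,0.291,0.060,0.0044,0.277,0.0371
spleen,0.207,0.579,0.0077,0.0113,0.097,0.0026
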