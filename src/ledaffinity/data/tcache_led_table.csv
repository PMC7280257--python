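# Torpedo californica acetylcholinesterase reference dataset.
# log_ki: base-10 logarithm of the experimentally measured inhibition
#   constant K_i, with K_i in nM (measurements at 22-25 C, pH 7.0-7.4).
# binding_energy, e_elstat, e_exch, e_ct, e_disp: DLPNO-CCSD(T)/def2-SVP
#   (NormalPNO) inter-fragment binding energy and LED contributions for the
#   3.5-A active-site cluster of each complex, in kcal/mol, stabilizing
#   contributions positive. e_ct sums both charge-transfer directions;
#   e_disp sums strong- and weak-pair dispersion.
# The GNT/1W6R complex (K_i measured at pH 8.0) is excluded as incommensurate.
complex_id,ligand,log_ki,binding_energy,e_elstat,e_exch,e_ct,e_disp
3ZV7,NHG,3.079,81.767,50.900,13.564,8.025,14.784
5NAU,DZ0,1.475,49.015,28.012,8.192,4.639,11.611
1U65,CP0,1.415,201.247,112.476,36.497,17.648,46.225
5NAP,DZ7,1.046,19.606,12.764,2.953,2.989,3.577
1H23,E12,0.653,220.404,138.560,34.812,19.335,41.187
1H22,E10,-0.097,243.558,154.083,38.869,23.252,44.367
1E66,HUX,-0.886,147.440,74.542,28.487,10.764,39.633
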