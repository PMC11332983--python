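# Cumulative probability of functional-decline onset by age and CAG.
# SYNTHETIC DIGITIZATION STAND-IN generated from logistic curves
# (mu,s): CAG40=(62,7.5) CAG45=(48,6) CAG50=(40,5); it is not source
# cohort data and exists so the prefunctional pipeline is runnable.
cag,age,cumulative_probability
40,25,0.007151
40,30,0.013834
40,35,0.026597
40,40,0.050530
40,45,0.093921
40,50,0.167982
40,55,0.282249
40,60,0.433726
40,65,0.598688
40,70,0.743962
40,75,0.849838
40,80,0.916827
40,85,0.955497
40,90,0.976645
40,95,0.987872
45,25,0.021179
45,30,0.047426
45,35,0.102784
45,40,0.208609
45,45,0.377541
45,50,0.582570
45,55,0.762542
45,60,0.880797
45,65,0.944451
45,70,0.975076
45,75,0.989013
45,80,0.995195
45,85,0.997906
45,90,0.999089
45,95,0.999604
50,25,0.047426
50,30,0.119203
50,35,0.268941
50,40,0.500000
50,45,0.731059
50,50,0.880797
50,55,0.952574
50,60,0.982014
50,65,0.993307
50,70,0.997527
50,75,0.999089
50,80,0.999665
50,85,0.999877
50,90,0.999955
50,95,0.999983
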