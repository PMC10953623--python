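# ventra linear SVM model
format_version: 1
features: apr_log,total_vv_norm,lr_frontal_log,lr_temporal_log,age,sex_code
mean: 0.060536363695769389 0.070180951587676177 -7.4703331215511538e-06 -0.00071105298376659195 66.327577341666768 0.55666666666666664
std: 0.083107763205835503 0.010603619934110164 0.07179259362214499 0.024982930227474227 9.3958971803388049 0.49677851089684721
weights: 0.31139839084923704 0.42844765593253337 -0.03800536251672329 -0.022279753308376324 -0.071319750597204426 0.052903638179931801
bias: -0.013750446368415279
C: 1
class_weight: balanced
n_per_class: 0=150 1=150
seed: 0
training_accuracy: 0.96666666666666667
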