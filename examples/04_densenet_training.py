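"""Train desk-scale dose-only and joint-fusion DenseNet classifiers.

Uses a strongly-planted phantom cohort at reduced resolution (12^3 input,
narrow DenseNet trunk) so a CPU run finishes in about two minutes.  The
default full-width configuration (initial 64 channels, growth 32, 3x12
layers -> 688 image features) is printed for reference but not trained here.
"""

import numpy as np

from dosemap_ntcp import preprocess as pp, synthetic_cohort as sc
from dosemap_ntcp.nn import (
    ArchitectureConfig, Hyperparameters, build_dose_only, build_joint_fusion,
    feature_dimension, fused_dimension, parameter_count, train,
)
from dosemap_ntcp.nn.train import scale_clinical, validation_auroc

full = ArchitectureConfig()
print(f"full-width 3D DenseNet-40: {feature_dimension(full)} image features, "
      f"{fused_dimension(full)} fused with the 6 clinical covariates, "
      f"{parameter_count(full):,} parameters")

config = sc.PhantomConfig(grid_shape=(16, 16, 16), seed=7)
truth = sc.PlantedTruth(beta0=-18.0, beta_dose=0.45, beta_clinical={})
cohort = sc.generate_population(config, truth, 200)
y = cohort.labels()

maps = [
    pp.preprocess_subject(
        s.dose, s.mask, pp.EQD2Params(3.0, s.record.n_fractions), None,
        (12, 12, 12), margin=1,
    )
    for s in cohort.subjects
]
stats = pp.fit_normalisation([m.values for m in maps])
x = np.stack([pp.apply_normalisation(m.values, stats) * m.mask for m in maps])[:, None]
clinical, _ = scale_clinical(cohort.clinical_table())

rng = np.random.default_rng(0)
idx = rng.permutation(200)
tr, va = idx[:150], idx[150:]

desk = ArchitectureConfig(initial_channels=8, growth_rate=4,
                          layers_per_block=(2, 2, 2), dropout=0.1)
hp = Hyperparameters(dropout=0.1, learning_rate=0.003, batch_size=16,
                     weight_decay=1e-4, epochs=25, seed=0)

dose_model = build_dose_only(desk, seed=1)
trained = train(dose_model, x[tr], y[tr], hp)
print(f"dose-only: loss {trained.history[0]:.2f} -> {trained.history[-1]:.2f}, "
      f"validation AUROC {validation_auroc(dose_model, x[va], y[va]):.2f} "
      "(>0.8 means the net recovered the planted dose-toxicity signal)")

fusion_model = build_joint_fusion(desk, seed=1)
trained_f = train(fusion_model, x[tr], y[tr], hp, clinical=clinical[tr])
print(f"joint fusion: validation AUROC "
      f"{validation_auroc(fusion_model, x[va], y[va], clinical[va]):.2f} "
      "(clinical covariates carry no signal under this truth, so the two "
      "models should land close together)")
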