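"""Train the dual-task network and forecast a patient's future scores.

Runs the three training phases (SiVE pretraining, subtype classification,
joint teacher-forced training) on a small well-separated cohort, then asks
the trained model for a 4-step (2-year) autoregressive forecast of one test
participant's MDS-UPDRS I-III totals.  Takes a minute or two on one CPU.
"""

import numpy as np

from pdprog import (
    GeneratorConfig,
    LossConfig,
    PhaseSchedule,
    build_model,
    build_samples,
    class_weights_from,
    default_profiles,
    fit_normalization,
    generate,
    impute,
    normalize,
    parameter_count_table,
    predict,
    split_cohort,
    train,
)

cfg = GeneratorConfig(
    n_per_subtype={"rapid": 40, "moderate": 40, "slow": 40, "HC": 40},
    visit_count_range=(6, 10), profiles=default_profiles(noise_sd=0.5), seed=1)
cohort, labels = generate(cfg)
imputed = impute(cohort)
train_ids, test_ids = split_cohort(labels, 0.25, seed=1)
stats = fit_normalization(imputed.subset(train_ids))
normalized = normalize(imputed, stats)

model = build_model(seed=1)
print(f"deployed trainable parameters: "
      f"{parameter_count_table(model)['deployed_total']:,}")

samples = build_samples(imputed.subset(train_ids), labels,
                        input_cohort=normalized.subset(train_ids))
visits = np.concatenate(
    [[v.values for v in p.visits] for p in normalized.subset(train_ids).participants])
schedule = PhaseSchedule(
    epochs=(15, 15, 40),
    loss=LossConfig(class_weights=class_weights_from(labels, train_ids), e_thres=8),
    max_samples_per_epoch=4096)
for phase, data in ((1, visits), (2, samples), (3, samples)):
    trace = train(model, data, schedule, phase, seed=phase)
    print(f"phase {phase}: loss {trace[0]:.3f} -> {trace[-1]:.3f} "
          f"over {len(trace)} epochs")

# forecast for one held-out participant from their first 3 visits
test_samples = build_samples(imputed.subset(test_ids[:1]), labels,
                             windows=(3,), max_horizon=4,
                             input_cohort=normalized.subset(test_ids[:1]))
s = next(t for t in test_samples if t.horizon == 4)
probs, forecast = predict(model, s.input_vectors, s.context_triplet, horizon=4)
names = ("rapid", "moderate", "slow", "HC")
print(f"\nparticipant {s.participant_id} (true subtype "
      f"{labels[s.participant_id].value}):")
print("  subtype probabilities:",
      ", ".join(f"{n}={p:.2f}" for n, p in zip(names, probs)))
print("  forecast vs truth (UPDRS I/II/III totals):")
for h in range(4):
    f, t = forecast[h], s.target_triplets[h]
    print(f"  +{6 * (h + 1):2d} months: predicted "
          f"({f[0]:5.1f}, {f[1]:5.1f}, {f[2]:5.1f})  "
          f"true ({t[0]:5.1f}, {t[1]:5.1f}, {t[2]:5.1f})")
print("each step feeds the previous prediction back into the decoder")
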