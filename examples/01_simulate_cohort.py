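"""Generate a synthetic two-cohort study and look at its ground truth.

The generator plants outcome-associated copy-number regions (gains/losses) in
patient subsets, makes expression probes inside those regions track copy
number, and draws poor outcomes from a logistic model in carrier status.
"""

import cnvsig

study = cnvsig.simulate_study(seed=7)

print("Planted regions (truth):")
for region in study.regions:
    carriers = int(study.train_carriers.loc[region.label].sum())
    print(f"  {region.label:<22} prevalence {region.prevalence:.2f} "
          f"effect log-odds {region.effect_log_odds:g} "
          f"-> {carriers}/{study.config.n_train} training carriers")

poor = study.train_outcomes["death_from_disease_flag"].mean()
print(f"\nTraining copy-number matrix: {study.train_cn.shape} (clones x samples), "
      f"{study.train_cn.isna().to_numpy().mean():.1%} missing entries")
print(f"Expression: {study.train_expr.shape[0]} probes; "
      f"{sum(len(v) for v in study.dosage_probe_ids.values())} are planted dosage probes")
print(f"Disease-death fraction in training cohort: {poor:.2f}")
print("\nValidation batches:",
      {k: int(v) for k, v in study.val_batches.value_counts().items()})
print("A second-batch effect (per-gene multiplicative) is applied to val2 — "
      "downstream normalization must undo it.")
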