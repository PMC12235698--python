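"""Train tiny pair-biased and base models and compare them.

A shortened version of the desk-scale ablation: both variants train for the
same small step budget on 3,000 synthetic spectra, then are scored by
peptide precision at 100% coverage on 200 held-out spectra. Expect a few
minutes on one CPU; the pair-biased variant should reach a lower training
loss and higher precision at this (mid-training) budget.
"""

from pairnovo import ModelConfig, SimConfig, TrainConfig, fit, generate_dataset
from pairnovo.evaluate import precision_at_coverage, score_predictions
from pairnovo.synthetic_data import default_dictionary

sim = SimConfig(seed=0)
dictionary = default_dictionary(sim)
data = generate_dataset(3_000, sim)
train, val = data[:2_800], data[2_800:]
test = generate_dataset(200, SimConfig(seed=1))

for variant in ("pa", "base"):
    result = fit(train, val, ModelConfig.tiny(variant),
                 TrainConfig.tiny(seed=0, max_steps=1_000), dictionary=dictionary)
    preds = result.model.decode_greedy(test)
    results = score_predictions(preds, test, dictionary)
    precision = precision_at_coverage(results, 1.0)
    final_loss = result.history[-1]["train_loss"]
    print(f"{variant:>4}: final train loss {final_loss:.3f}, "
          f"test peptide precision {precision:.3f}")
print()
print("Peptide precision = exactly correct peptides / all test spectra.")
print("The pairwise attention bias hands the encoder every m/z difference,")
print("so it does not have to learn subtraction from absolute encodings —")
print("at equal budgets it converges faster than the base model.")
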