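"""Draw the study dataset: a TEDS-D-like synthetic cohort with known truth.

Generates n=20,000 discharge-like records from the packaged hard scenario
(main effects + five pairwise interactions + a two-predictor threshold
effect, intercept calibrated to 45.2% treatment success), reports the
realized prevalence and the scenario's Bayes-optimal AUC ceiling, and
writes the dataset, schema, and ground-truth coefficients under results/.
"""

from pathlib import Path

import yaml

from sudlearn.schema import save_schema, write_dataset
from sudlearn.simulate import generate, oracle_auc, preset

SEED = 2026
N = 20_000

out = Path(__file__).resolve().parents[1] / "results" / "data"
out.mkdir(parents=True, exist_ok=True)

scenario = preset("interactions-nonlinear")
data = generate(scenario.config, N, seed=SEED)
write_dataset(data, out / "data.csv")
save_schema(scenario.config.schema, out / "schema.yaml")

truth = {
    "preset": scenario.name,
    "seed": SEED,
    "n": N,
    "intercept": float(scenario.config.intercept),
    "main_effects": {
        k: {l: float(b) for l, b in v.items()}
        for k, v in scenario.config.main_effects.items()
    },
    "interaction_effects": [
        [a, la, b, lb, float(beta)]
        for a, la, b, lb, beta in scenario.config.interaction_effects
    ],
}
(out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))

ceiling = oracle_auc(scenario.config, 100_000, seed=SEED)
print(f"wrote {data.n} records to {out / 'data.csv'}")
print(f"treatment-success prevalence: {data.outcome.mean():.3f} (target 0.452)")
print(f"Bayes-optimal AUC ceiling of the scenario: {ceiling:.3f}")
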