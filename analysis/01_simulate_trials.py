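"""Simulate the two virtual studies used throughout the analysis.

Writes NONMEM-style CSVs and the generating-model JSONs under
results/datasets/.  Phase-I-like: 255 healthy men, one 35 mg SC dose, 23
rich samples; phase-III-like: 555 postmenopausal women, 60 mg SC every 6
months, 6 sparse samples.
"""

import json
from pathlib import Path

from denopk import dataset_io, estimation, reference, synthetic_trial

SEED = 20250926
OUT = Path("results/datasets")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = [
        ("phase1", synthetic_trial.phase1_design(seed=SEED), reference.phase1_reference_model()),
        ("phase3", synthetic_trial.phase3_design(seed=SEED + 1), reference.pooled_reference_model()),
    ]
    for name, design, truth in specs:
        trial = synthetic_trial.simulate_trial(design, truth)
        path = OUT / f"{name}.csv"
        dataset_io.write_dataset(trial.subjects, path)
        (OUT / f"{name}_truth.json").write_text(
            json.dumps(estimation.model_to_dict(truth), indent=2)
        )
        n_obs = sum(s.n_obs for s in trial.subjects)
        n_blq = int(sum(s.blq.sum() for s in trial.subjects))
        print(
            f"{name}: {len(trial.subjects)} subjects, {n_obs} scheduled samples, "
            f"{n_blq} below LLOQ -> {path}"
        )


if __name__ == "__main__":
    main()
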