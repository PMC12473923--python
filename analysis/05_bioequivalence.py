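"""Model-based bioequivalence of the three phase-I arms.

Per-subject Cmax, AUC0-tau and AUC0-inf come from the empirical-Bayes
individual profiles under the fitted phase-I model; each reference arm is
compared with the test arm via the geometric mean ratio and a Welch-t 90%
CI against the 80-125% margin.  All arms were simulated from identical
parameters, so every comparison is expected to pass.
"""

import json
from pathlib import Path

from denopk import dataset_io, derived_pk, estimation

OUT = Path("results/be")
TAU = 253.0  # last scheduled sampling day of the single-dose study


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = dataset_io.read_dataset("results/datasets/phase1.csv")
    subjects, _ = dataset_io.apply_blq_policy_all(subjects)
    model = estimation.model_from_dict(
        json.loads(Path("results/fits/phase1_fit.json").read_text())["model"]
    )
    table = {}
    for ref_arm in (2, 3):
        res = derived_pk.be_analysis(model, subjects, test_arm=1, ref_arm=ref_arm, tau=TAU)
        for metric, r in res.items():
            key = f"arm{ref_arm}_vs_arm1_{metric}"
            table[key] = dict(gmr_pct=r.gmr_pct, ci90_pct=list(r.ci90_pct), passed=r.passed)
            print(
                f"{key}: GMR {r.gmr_pct:.1f}% CI90 "
                f"[{r.ci90_pct[0]:.1f}, {r.ci90_pct[1]:.1f}] {'PASS' if r.passed else 'FAIL'}"
            )
    (OUT / "be_35mg.json").write_text(json.dumps(table, indent=2))


if __name__ == "__main__":
    main()
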