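"""Classify OTUs into incorporation ecotypes and score recovery of the
planted truth.

Runs the full pipeline at the chosen incubation time, applies the >1 %
abundance filter and the three-type classifier to the representative
H/L fractions and the in-situ sample, and compares calls against the
planted incorporator types. Writes results/ecotype_calls.tsv and
results/ecotype_recovery.json.
"""

import argparse
import json
import warnings
from pathlib import Path

from dnasip.ecotypes import calls_frame
from dnasip.pipeline import RunConfig, incorporation_confusion, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(RunConfig(seed=args.seed))
    calls_frame(res.calls).to_csv(out / "ecotype_calls.tsv", sep="\t", index=False)
    res.summary.to_csv(out / "ecotype_summary.tsv", sep="\t")

    truth = {tx.taxon_id: tx.true_type for tx in res.experiment.community}
    conf = incorporation_confusion(res.calls, truth)
    n_by_type = {}
    for c in res.calls:
        n_by_type[c.ecotype] = n_by_type.get(c.ecotype, 0) + 1
    recovery = {
        "chosen_timepoint_days": res.decision.chosen_t,
        "n_otus_classified": len(res.calls),
        "calls_by_type": n_by_type,
        **{k: (None if v != v else v) for k, v in conf.items()},
    }
    (out / "ecotype_recovery.json").write_text(json.dumps(recovery, indent=1))

    print(f"chosen timepoint: {res.decision.chosen_t} d")
    print(f"{len(res.calls)} OTUs passed the >1% filter; calls: {n_by_type}")
    print(f"type-I sensitivity among classified rapid taxa: {conf['type_I_sensitivity']}")
    print(f"incorporation false-positive rate: {conf['incorporation_fpr']}")
    print(f"wrote {out}/ecotype_calls.tsv, ecotype_summary.tsv, ecotype_recovery.json")


if __name__ == "__main__":
    main()
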