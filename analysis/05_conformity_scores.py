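"""Score each patient's regional morphometry against the patient-group model.

The conformity score of patient s in region r is the log-likelihood of
the patient's residual data point under the region's patient-group
Gaussian fit: higher means more typical, lower means more of an outlier.
Writes the subjects-by-regions score table and prints the most and least
typical patients on average.
"""

import argparse
from pathlib import Path

from morphohet import gaussian, registry, synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--residuals", type=Path, default=Path("results/residuals.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    regions = synthetic._subset_registry(synthetic.SCENARIO_REGIONS)
    resid = registry.read_morphometry_table(args.residuals, regions)
    et = resid[resid["group"] == "ET_pre"].reset_index(drop=True)
    scores, flagged = gaussian.conformity_scores(et, regions)
    args.out.mkdir(parents=True, exist_ok=True)
    registry.write_table(scores.reset_index(), args.out / "conformity.tsv")

    mean_scores = scores.mean(axis=1).sort_values()
    print(f"conformity scores for {scores.shape[0]} patients x {scores.shape[1]} regions"
          + (f" ({len(flagged)} regions withheld)" if flagged else ""))
    print("least typical patients:", ", ".join(
        f"{s} ({v:.2f})" for s, v in mean_scores.head(3).items()))
    print("most typical patients:", ", ".join(
        f"{s} ({v:.2f})" for s, v in mean_scores.tail(3).items()))


if __name__ == "__main__":
    main()
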