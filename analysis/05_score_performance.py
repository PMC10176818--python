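"""Per-score prognostic performance within each stratum.

Validates CTP, MELD and MELD-Na in both strata, CLIF-C ACLF within the
ACLF stratum and CLIF-C AD within the AD stratum (each CLIF-C score is
specific to its target population): DeLong AUC with 95% CI, Youden cutoff
with sensitivity/specificity/PPV/NPV, Hosmer-Lemeshow calibration, Brier
score and Nagelkerke R² on logistic-recalibrated probabilities.
"""

from pathlib import Path

import pandas as pd

from avbrisk.pipeline import performance_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scored = pd.read_csv(RESULTS / "scored.csv")
    for stratum in ("ACLF", "AD"):
        table = performance_table(scored, stratum)
        path = RESULTS / f"performance_{stratum.lower()}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        print(f"\n{stratum} stratum (n = {int(table.n.iloc[0])}) -> {path}")
        cols = ["score_name", "auc", "auc_ci_low", "auc_ci_high", "cutoff",
                "youden", "sensitivity", "specificity", "brier", "r_squared", "hl_p"]
        print(table[cols].round(3).to_string(index=False))
        best = table.loc[table.auc.idxmax()]
        print(f"best discrimination: {best.score_name} (AUC {best.auc:.3f})")


if __name__ == "__main__":
    main()
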