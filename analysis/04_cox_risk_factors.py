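"""Cox regression for 42-day mortality: univariate screen and backward
stepwise multivariate selection.

The question of interest is whether the ACLF indicator remains an
independent risk factor after adjustment for the routine clinical
covariates (vitals, labs, ascites, demographics).
"""

from pathlib import Path

import pandas as pd

from avbrisk.pipeline import cox_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scored = pd.read_csv(RESULTS / "scored.csv")
    uni, multi, final = cox_tables(scored)
    uni.to_csv(RESULTS / "cox_univariate.csv", index=False, float_format="%.6g")
    multi.to_csv(RESULTS / "cox_multivariate.csv", index=False, float_format="%.6g")

    screened = uni[uni.p < 0.05]
    print(f"univariate screen: {len(screened)}/{len(uni)} candidates at p < 0.05")
    print("final multivariate model:")
    print(multi.to_string(index=False))
    if "has_aclf" in final.covariates:
        hr = final.hazard_ratio["has_aclf"]
        lo, hi = final.ci_low["has_aclf"], final.ci_high["has_aclf"]
        print(f"ACLF remains independently prognostic: "
              f"HR {hr:.2f} (95% CI {lo:.2f}-{hi:.2f}, p = {final.p_value['has_aclf']:.3g})")
    else:
        print("ACLF indicator was not retained in the final model")


if __name__ == "__main__":
    main()
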