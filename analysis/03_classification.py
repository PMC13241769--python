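"""Cross-validated logistic models: clinical-only vs clinical + qEEG.

Fits both models with stratified 5-fold CV, reports AUC, threshold
metrics and coefficient saliences, and tests the added value of the
qEEG block with the row-permutation comparison. Writes results/model.json
and the averaged ROC curves to results/roc.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from netsig import pipeline
from netsig.cli import _jsonable, _read_features
from netsig.io import read_clinical_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    features = _read_features(args.results)
    clinical = read_clinical_csv(args.results / "clinical.csv")
    rep = pipeline.run_classify(features, clinical, n_perm=args.n_perm,
                                seed=args.seed)

    print(f"clinical-only model      AUC = {rep['auc_clin']:.3f} "
          f"± {rep['auc_clin_sd']:.3f}")
    print(f"clinical + qEEG model    AUC = {rep['auc_full']:.3f} "
          f"± {rep['auc_full_sd']:.3f}")
    print(f"added value of qEEG:     dAUC = {rep['delta_auc']:+.3f}, "
          f"permutation p = {rep['comparison_p']:.4g} "
          f"({rep['n_perm']} permutations)")
    m, s = rep["metrics_full_median"], rep["metrics_full_sd"]
    print("clinical+qEEG threshold metrics (median ± sd over folds):")
    print("  " + "  ".join(f"{k}={m[k]:.2f}±{s[k]:.2f}"
                           for k in ("sens", "spec", "ppv", "npv",
                                     "acc", "f1")))
    print("top feature saliences (|beta|, standardized):")
    for srow in rep["saliences"][:5]:
        print(f"  {srow['feature']:28s} |beta|={srow['abs_beta']:.2f} "
              f"p={srow['p']:.2g}")

    roc = rep.pop("roc")
    (args.results / "model.json").write_text(
        json.dumps(rep, indent=1, default=_jsonable))
    pd.DataFrame(roc).to_csv(args.results / "roc.csv", index=False)
    print(f"model report -> {args.results / 'model.json'}; "
          f"ROC -> {args.results / 'roc.csv'}")


if __name__ == "__main__":
    main()
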