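"""End-to-end orchestration: extract → stats → classify.

Feature extraction maps each recording through preprocessing, spectral,
connectivity and graph modules into one tidy feature table; it never
sees the clinical outcome (extraction is blinded by interface). The
statistics stage runs group permutation tests with BH-FDR, the
band × group split-plot ANOVA and channel-wise maps; the classification
stage fits and compares the clinical-only and clinical+qEEG logistic
models.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from netsig import classify, connectivity, graphnet, io, spectral, stats
from netsig.errors import NetsigError, ParameterError

logger = logging.getLogger("netsig")

#: Default qEEG block for the clinical+qEEG model: the global features
#: that separate the groups in the directional study conditions.
DEFAULT_QEEG_FEATURES = [
    "rel_power:delta", "rel_power:alpha", "exponent:", "offset:",
    "btwc:delta", "btwc:alpha", "swi:delta", "ge:delta",
]

CLINICAL_PREDICTORS = [
    "sex_female", "focal_epilepsy", "structural_etiology",
    "neuroimaging_abnormality", "tle", "response_first_asm",
    "age", "age_onset", "epilepsy_duration",
    "baseline_seizure_freq", "n_seizure_types",
]


def extract_subject_features(rec: io.Recording, subject_id: str,
                             bands: dict | None = None,
                             epoch_target: float = 180.0,
                             epoch_tol: float = 25.0,
                             density: float = 0.05,
                             n_null: int = 20,
                             graph_seed: int = 0,
                             keep_mask: np.ndarray | None = None,
                             ) -> pd.DataFrame:
    """Full qEEG feature set for one recording, as tidy rows."""
    bands = dict(bands or spectral.DEFAULT_BANDS)
    rec = io.rereference_average(rec)
    rec = io.filter_recording(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        epochs = io.select_epochs(rec, keep_mask=keep_mask,
                                  target=epoch_target, tol=epoch_tol)

    rows = []

    def add(metric, band, scope, channel, value):
        rows.append({"subject_id": subject_id, "metric": metric,
                     "band": band or "", "scope": scope,
                     "channel": channel or "", "value": float(value)})

    spec = spectral.welch_psd(rec, epochs)
    bp = spectral.band_relative_power(spec, bands)
    for j, name in enumerate(bp.bands):
        add("rel_power", name, "GLOBAL", None, bp.global_[name])
        for c, lab in enumerate(rec.labels):
            add("rel_power", name, "channel", lab, bp.per_channel[c, j])
    ap = spectral.fit_aperiodic(spec)
    add("exponent", None, "GLOBAL", None, ap.exponent_global)
    add("offset", None, "GLOBAL", None, ap.offset_global)
    for c, lab in enumerate(rec.labels):
        add("exponent", None, "channel", lab, ap.exponent[c])
        add("offset", None, "channel", lab, ap.offset[c])

    cs = connectivity.cross_spectra(rec, epochs)
    for name, band in bands.items():
        cm = connectivity.wpli(cs, band)
        add("wpli_global", name, "GLOBAL", None, connectivity.global_wpli(cm))
        A = graphnet.binarize_top_edges(cm, density=density)
        gm = graphnet.graph_metrics(A, n_null=n_null, seed=graph_seed)
        add("modularity", name, "GLOBAL", None, gm.modularity)
        add("swi", name, "GLOBAL", None, gm.swi)
        add("btwc", name, "GLOBAL", None, gm.btwc)
        add("ge", name, "GLOBAL", None, gm.ge)
        add("clustering", name, "GLOBAL", None, gm.clustering)
        add("lambda", name, "GLOBAL", None, gm.path_length)
    return pd.DataFrame(rows)


def extract_features(recordings, subject_ids=None, max_failure_rate: float = 0.2,
                     **kwargs) -> pd.DataFrame:
    """Feature table for a cohort of recordings.

    Per-subject failures are logged and skipped; more than
    ``max_failure_rate`` failures abort the run. The clinical table (and
    in particular the outcome label) is never an input to extraction.
    """
    if subject_ids is None:
        subject_ids = [rec.meta.get("subject_id", f"S{i:03d}")
                       for i, rec in enumerate(recordings)]
    frames, failures = [], 0
    for rec, sid in zip(recordings, subject_ids):
        try:
            frames.append(extract_subject_features(rec, sid, **kwargs))
        except NetsigError as exc:
            failures += 1
            logger.warning("subject %s skipped: %s", sid, exc)
    if not frames:
        raise ParameterError("no subject could be processed")
    if failures > max_failure_rate * len(recordings):
        raise ParameterError(
            f"{failures}/{len(recordings)} subjects failed extraction")
    return pd.concat(frames, ignore_index=True)


def features_wide(features: pd.DataFrame) -> pd.DataFrame:
    """GLOBAL-scope features pivoted to one row per subject; columns are
    ``metric:band`` keys (band empty for broadband metrics)."""
    g = features[features["scope"] == "GLOBAL"].copy()
    g["key"] = g["metric"] + ":" + g["band"].fillna("")
    wide = g.pivot_table(index="subject_id", columns="key", values="value",
                         aggfunc="first")
    return wide


def _check_ids(wide: pd.DataFrame, clinical: pd.DataFrame):
    feat_ids = set(wide.index)
    clin_ids = set(clinical["subject_id"])
    if feat_ids != clin_ids:
        missing = sorted(feat_ids ^ clin_ids)
        raise ParameterError(f"unmatched subject ids: {missing}")


def run_stats(features: pd.DataFrame, clinical: pd.DataFrame,
              n_perm: int = 10_000, seed: int = 0, q: float = 0.05,
              modal_repeats: int = 100, channel_n_perm: int = 2_000) -> dict:
    """The group-statistics layer on an extracted cohort.

    Global features: two-sided permutation test per feature via the
    modal-p wrapper, BH-FDR across features. Relative band power and
    global wPLI additionally get the band × group split-plot ANOVA.
    Channel-wise relative power, exponent and offset get permutation
    maps with BH correction across channels × bands.
    """
    if features.empty:
        raise ParameterError("empty feature table")
    wide = features_wide(features)
    _check_ids(wide, clinical)
    clin = clinical.set_index("subject_id").loc[wide.index]
    y = clin["outcome"].to_numpy()

    report: dict = {"n_perm": n_perm, "seed": seed, "q": q,
                    "groups": {"A(DRE-like)": int(y.sum()),
                               "B": int((1 - y).sum())}}

    feature_tests = {}
    keys = sorted(wide.columns)
    ss = np.random.SeedSequence((seed, 1))
    for key, sub_ss in zip(keys, ss.spawn(len(keys))):
        vals = wide[key].to_numpy()
        ok = np.isfinite(vals)
        x, yv = vals[ok & (y == 1)], vals[ok & (y == 0)]
        if min(len(x), len(yv)) < 2:
            continue
        base_seed = int(sub_ss.generate_state(1)[0] % (2 ** 31 - 1))
        obs = float(np.mean(x) - np.mean(yv))
        p = stats.modal_p(
            lambda s, x=x, yv=yv: stats.permutation_test(
                x, yv, n_perm=n_perm, seed=s).p,
            n_repeats=modal_repeats, seed=base_seed)
        feature_tests[key] = {"mean_diff": obs, "p": p}
    fdr = stats.bh_fdr(np.array([t["p"] for t in feature_tests.values()]), q=q)
    for (key, t), adj, rej in zip(feature_tests.items(), fdr.adjusted,
                                  fdr.rejected):
        t["p_adjusted"] = float(adj)
        t["significant"] = bool(rej)
    report["global_features"] = feature_tests

    band_order = ["delta", "theta", "alpha", "beta"]
    anovas = {}
    for metric in ("rel_power", "wpli_global"):
        cols = [f"{metric}:{b}" for b in band_order]
        if not all(c in wide.columns for c in cols):
            continue
        data = wide[cols].to_numpy()
        res = stats.mixed_anova(data, y)
        anovas[metric] = {
            eff: {"F": e.f, "df": e.df, "p": e.p, "p_gg": e.p_gg}
            for eff, e in res.effects.items()}
        anovas[metric]["gg_epsilon"] = res.gg_epsilon
        anovas[metric]["mauchly_w"] = res.mauchly_w
        anovas[metric]["mauchly_p"] = res.mauchly_p
        anovas[metric]["bartlett_p"] = res.bartlett_p
    report["anova"] = anovas

    # second between-subject factor (structural brain abnormalities),
    # applied separately per frequency band
    two = {}
    if "sba_present" in clin.columns and clin["sba_present"].nunique() == 2:
        sba = clin["sba_present"].to_numpy()
        for band in band_order:
            key = f"rel_power:{band}"
            if key not in wide.columns:
                continue
            try:
                res = stats.twoway_anova(wide[key].to_numpy(), y, sba)
            except ParameterError:
                continue
            two[key] = {"group": res["a"], "sba": res["b"],
                        "interaction": res["interaction"]}
    report["anova_group_by_sba"] = two

    chan = features[features["scope"] == "channel"].copy()
    maps = {}
    if not chan.empty:
        mats = {}
        for (metric, band), sub in chan.groupby(["metric", "band"]):
            piv = sub.pivot_table(index="subject_id", columns="channel",
                                  values="value").loc[wide.index]
            mats[f"{metric}:{band}"] = piv.to_numpy()
        cw_seed = int(np.random.SeedSequence((seed, 2)).generate_state(1)[0]
                      % (2 ** 31 - 1))
        cw = stats.channelwise_group_test(mats, y, n_perm=channel_n_perm,
                                          seed=cw_seed, q=q)
        maps = {"n_tests": len(cw["p"]),
                "n_significant": int(cw["rejected"].sum()),
                "families": sorted({name for name, _ in cw["index"]})}
    report["channelwise"] = maps

    cat = {}
    for col in ("sex_female", "structural_etiology", "response_first_asm"):
        if col in clin.columns:
            tab = pd.crosstab(y, clin[col]).to_numpy()
            if tab.shape == (2, 2) and (tab.sum(0) > 0).all() and (tab.sum(1) > 0).all():
                s, df, p = stats.chi2_contingency(tab)
                cat[col] = {"chi2": s, "df": df, "p": p}
    report["categorical"] = cat
    return report


def run_classify(features: pd.DataFrame, clinical: pd.DataFrame,
                 qeeg_features=None, k: int = 5, n_perm: int = 1_000,
                 seed: int = 0) -> dict:
    """Fit and compare the clinical-only and clinical+qEEG models."""
    wide = features_wide(features)
    _check_ids(wide, clinical)
    clin = clinical.set_index("subject_id").loc[wide.index]
    y = clin["outcome"].to_numpy(dtype=float)

    clin_cols = [c for c in CLINICAL_PREDICTORS if c in clin.columns]
    X_clin = clin[clin_cols].to_numpy(dtype=float)

    qeeg_features = list(qeeg_features or DEFAULT_QEEG_FEATURES)
    missing = [f for f in qeeg_features if f not in wide.columns]
    if missing:
        raise ParameterError(f"qEEG features absent from table: {missing}")
    X_qeeg = wide[qeeg_features].to_numpy(dtype=float)
    # median imputation for undefined metrics (e.g. SWI on degenerate graphs)
    for j in range(X_qeeg.shape[1]):
        col = X_qeeg[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmedian(col)

    res_clin = classify.crossval_roc(X_clin, y, k=k, seed=seed,
                                     feature_names=clin_cols)
    X_full = np.column_stack([X_clin, X_qeeg])
    res_full = classify.crossval_roc(X_full, y, k=k, seed=seed,
                                     feature_names=clin_cols + qeeg_features)
    comp = classify.compare_models(X_clin, X_qeeg, y, k=k, n_perm=n_perm,
                                   seed=seed)

    sal = sorted(zip(res_full.feature_names, res_full.fit.saliences,
                     res_full.fit.p[1:]), key=lambda t: -t[1])
    return {
        "auc_clin": res_clin.auc_mean, "auc_clin_sd": res_clin.auc_sd,
        "auc_full": res_full.auc_mean, "auc_full_sd": res_full.auc_sd,
        "delta_auc": comp.delta_auc, "comparison_p": comp.p,
        "n_perm": comp.n_perm, "seed": seed,
        "metrics_full_median": res_full.metrics_median,
        "metrics_full_sd": res_full.metrics_sd,
        "saliences": [{"feature": f, "abs_beta": float(b), "p": float(p)}
                      for f, b, p in sal],
        "roc": {"fpr": res_full.roc_fpr.tolist(),
                "tpr_full": res_full.roc_tpr.tolist(),
                "tpr_clin": res_clin.roc_tpr.tolist()},
    }
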