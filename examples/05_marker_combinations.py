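"""Two-marker combinations: logistic predicted-probability thresholds and
boolean union strata, ranked in one report."""

from admarker import endpoints as ep
from admarker import stratify, synth
from admarker.combos import enumerate_and_report

trial = synth.simulate_trial(synth.default_config(seed=30))
cohort = trial.cohort[trial.cohort["biomarker_consent"]]
endpoints = ep.compute_endpoints(cohort)
matrix = trial.proteome.loc[cohort["patient_id"]]

active = endpoints["arm"] == "high_dose"
flags = endpoints.loc[active, "easi50_wk4"].astype(bool).to_numpy()
deps = stratify.select_deps(
    matrix.loc[endpoints.loc[active, "patient_id"]], flags, auroc_min=0.7
)

report = enumerate_and_report(matrix, deps[:4], endpoints, k=2)
cols = ["stratum", "pathway", "delta_easi", "delta_easi_p", "pct_bas",
        "pp_auc", "ppv", "npv", "or", "or_p"]
print(report[cols].round(3).head(8).to_string(index=False))
print("\n'union' rows stratify by 'marker A^hi or marker B^lo' at the single-")
print("marker Youden cut-offs; 'pp' rows threshold the logistic predicted")
print("probability at its own Youden-optimal point. Rows are ranked by the")
print("odds-ratio Fisher p, then AUC.")
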